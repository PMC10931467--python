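"""Local stability and bifurcation diagnostics.

Stability of either equilibrium is read off the eigenvalues of the 6x6
Jacobian of the vector field. At the threshold R0 = 1 (reached by tuning
the contact rate phi to its critical value phi*) the Jacobian at the DFE
has a simple zero eigenvalue, and the direction of the emerging endemic
branch is decided by the centre-manifold normal-form coefficients

    a = 2 * v2 * w1 * w3 * phi* * chi        (a < 0)
    b = v2 * w3 * S0 * chi                   (b > 0)

where w and v are the right and left null vectors of J(phi*) and S0 is
the susceptible level at the DFE. a < 0 with b > 0 is a forward
(supercritical) bifurcation: a small, stable endemic state grows
continuously out of zero prevalence as R0 crosses 1, so there is no
bistable window below threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .equilibria import compute_R0, dfe, eep, phi_star
from .model import (
    DegenerateParameterError,
    InvalidInputError,
    ModelParameters,
    StateVector,
    _as_state_array,
)

__all__ = [
    "StabilityReport",
    "BifurcationCoefficients",
    "jacobian",
    "dfe_stability",
    "eep_stability",
    "routh_hurwitz_quadratic",
    "bifurcation_coefficients",
]


@dataclass(frozen=True)
class StabilityReport:
    equilibrium: StateVector
    eigenvalues: np.ndarray  # 6 complex numbers
    max_real_part: float
    verdict: str  # "stable" | "unstable" | "marginal"


@dataclass(frozen=True)
class BifurcationCoefficients:
    """Centre-manifold normal-form coefficients at the R0 = 1 threshold."""

    a: float
    b: float
    w: np.ndarray  # right null vector of J(phi*), w2 = 1
    v: np.ndarray  # left null vector, scaled so v . w = 1
    phi_star: float


def jacobian(state: Iterable[float], params: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of the vector field at ``state``.

    The only nonlinearity is the incidence term phi*chi*I1*S, which
    contributes -phi*chi*I1 and -phi*chi*S to the S-row (and their
    positives to the E-row); every other entry is a constant rate.
    """
    y = _as_state_array(state)
    S, _, I1, _, _, _ = y
    p = params
    pc = p.phi * p.chi
    return np.array([
        [-pc * I1 - p.beta - p.tau, 0.0, -pc * S, 0.0, p.zeta * p.lam, 0.0],
        [pc * I1, -p.sigma - p.tau, pc * S, 0.0, 0.0, 0.0],
        [0.0, p.Phi * p.sigma, -p.tau - p.alpha - p.psi, 0.0, 0.0, 0.0],
        [0.0, 0.0, p.alpha + p.psi * (1.0 - p.omega), -p.upsilon - p.rho - p.tau, 0.0, 0.0],
        [0.0, (1.0 - p.Phi) * p.sigma, p.omega * p.psi, p.upsilon, -p.tau - p.lam, 0.0],
        [p.beta, 0.0, 0.0, 0.0, (1.0 - p.zeta) * p.lam, -p.tau],
    ])


def _classify(equilibrium: StateVector, J: np.ndarray, tol: float) -> StabilityReport:
    eigenvalues = np.linalg.eigvals(J)
    max_real = float(np.max(eigenvalues.real))
    if max_real < -tol:
        verdict = "stable"
    elif max_real > tol:
        verdict = "unstable"
    else:
        verdict = "marginal"
    return StabilityReport(equilibrium=equilibrium, eigenvalues=eigenvalues,
                           max_real_part=max_real, verdict=verdict)


def dfe_stability(params: ModelParameters, tol: float = 1e-9) -> StabilityReport:
    """Eigenvalue classification of the addiction-free equilibrium.

    The spectrum always contains -tau and -(beta+tau) (the quitter and
    susceptible relaxation rates decouple); the sign of the leading
    eigenvalue tracks sign(R0 - 1), so the DFE is locally asymptotically
    stable exactly when R0 < 1.
    """
    report = dfe(params)
    return _classify(report.state, jacobian(report.state, params), tol)


def eep_stability(params: ModelParameters, tol: float = 1e-9) -> StabilityReport:
    """Eigenvalue classification of the endemic equilibrium.

    Raises
    ------
    DegenerateParameterError
        When no admissible endemic equilibrium exists (R0 <= 1).
    """
    report = eep(params)
    if report is None:
        raise DegenerateParameterError(
            f"no endemic equilibrium: R0 = {compute_R0(params):.6g} <= 1"
        )
    return _classify(report.state, jacobian(report.state, params), tol)


def routh_hurwitz_quadratic(a1: float, a2: float) -> bool:
    """Both roots of ``x^2 + a1*x + a2`` have negative real part iff a1, a2 > 0.

    This is the Routh–Hurwitz condition for the quadratic factor of the
    DFE characteristic polynomial, whose constant term factors as
    ``(sigma+tau)*(alpha+psi+tau)*(1 - R0)`` — positive exactly when
    R0 < 1.
    """
    return a1 > 0.0 and a2 > 0.0


def bifurcation_coefficients(params: ModelParameters, tol: float = 1e-8) -> BifurcationCoefficients:
    """Normal-form coefficients a, b at phi = phi*.

    The right null vector w of J(phi*) is solved row by row with the free
    scale fixed at w2 = 1; the left null vector has v1 = v4 = v5 = v6 = 0
    and v3 = (sigma+tau)/(Phi*sigma) * v2, with v2 chosen so v . w = 1.
    The signs of a and b are invariant to these scale choices.

    Raises
    ------
    DegenerateParameterError
        If the zero eigenvalue of J(phi*) is not simple.
    """
    p_star = params.replace(phi=phi_star(params))
    p = p_star
    S0 = p.Lambda / (p.beta + p.tau)

    # right null vector, w2 = 1, from the row balances of J(phi*) w = 0
    w2 = 1.0
    w3 = p.Phi * p.sigma * w2 / (p.tau + p.alpha + p.psi)
    w4 = (p.alpha + p.psi * (1.0 - p.omega)) * w3 / (p.upsilon + p.rho + p.tau)
    w5 = ((1.0 - p.Phi) * p.sigma * w2 + p.omega * p.psi * w3 + p.upsilon * w4) / (p.tau + p.lam)
    w1 = (p.zeta * p.lam * w5 - p.phi * p.chi * S0 * w3) / (p.beta + p.tau)
    w6 = (p.beta * w1 + (1.0 - p.zeta) * p.lam * w5) / p.tau
    w = np.array([w1, w2, w3, w4, w5, w6])

    # left null vector, then normalise v . w = 1
    v = np.zeros(6)
    v[1] = 1.0
    v[2] = (p.sigma + p.tau) / (p.Phi * p.sigma)
    v = v / float(v @ w)

    J = jacobian(dfe(p_star).state, p_star)
    if float(np.max(np.abs(J @ w))) > tol or float(np.max(np.abs(v @ J))) > tol:
        raise DegenerateParameterError("null vectors do not annihilate J(phi*); zero eigenvalue not simple?")
    eigs = np.sort(np.abs(np.linalg.eigvals(J).real))
    if eigs[1] < 1e-6:  # a second (near-)zero eigenvalue
        raise DegenerateParameterError("zero eigenvalue of J(phi*) is not simple")

    # Only the incidence term has nonzero second derivatives:
    # d2(dE/dt)/dS dI1 = phi*chi, and d2(dE/dt)/dI1 dphi = chi*S0.
    a = 2.0 * v[1] * w[0] * w[2] * p.phi * p.chi
    b = v[1] * w[2] * S0 * p.chi
    return BifurcationCoefficients(a=float(a), b=float(b), w=w, v=v, phi_star=p.phi)
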