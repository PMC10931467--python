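"""Equilibria and threshold quantities.

The model has two steady states in the feasible region: the addiction-free
equilibrium (DFE), where every compartment touched by addiction (E, I1,
I2, R) is empty, and — whenever the basic reproduction number R0 exceeds
one — a unique endemic equilibrium (EEP) with all compartments positive.

R0 has the closed form

    R0 = Lambda * sigma * phi * chi * Phi
         / ((alpha + psi + tau) * (beta + tau) * (sigma + tau))

and equivalently arises as the spectral radius of the next-generation
matrix F V^-1 built from the infected block (E, I1, I2, R) linearised at
the DFE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    DegenerateParameterError,
    ModelParameters,
    StateVector,
    rhs,
)

__all__ = [
    "EquilibriumReport",
    "compute_R0",
    "compute_R0_ngm",
    "ngm_matrices",
    "dfe",
    "eep",
    "strength_number",
    "phi_star",
]

#: components in (-ADMISSIBILITY_TOL, 0) are treated as exact zeros
ADMISSIBILITY_TOL = 1e-9


@dataclass(frozen=True)
class EquilibriumReport:
    """A steady state together with its diagnostics.

    Attributes
    ----------
    state : StateVector
        The equilibrium compartment sizes.
    kind : str
        ``"DFE"`` (addiction-free) or ``"EEP"`` (endemic).
    residual : float
        Max absolute component of the vector field at ``state``.
    admissible : bool
        True when all components are >= -1e-9 (tiny negative values are
        rounding noise and treated as zero).
    """

    state: StateVector
    kind: str
    residual: float
    admissible: bool


def compute_R0(params: ModelParameters) -> float:
    """Basic reproduction number from its closed form.

    Raises
    ------
    DegenerateParameterError
        If any factor of the denominator vanishes.
    """
    p = params
    denom_factors = {
        "alpha+psi+tau": p.alpha + p.psi + p.tau,
        "beta+tau": p.beta + p.tau,
        "sigma+tau": p.sigma + p.tau,
    }
    for name, value in denom_factors.items():
        if value == 0.0:
            raise DegenerateParameterError(f"R0 undefined: denominator factor ({name}) is zero")
    return (
        p.Lambda * p.sigma * p.phi * p.chi * p.Phi
        / (denom_factors["alpha+psi+tau"] * denom_factors["beta+tau"] * denom_factors["sigma+tau"])
    )


def ngm_matrices(params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """New-infection matrix F and transition matrix V at the DFE.

    Both are 4x4 on the infected block ordered (E, I1, I2, R). F holds the
    linearised rate of *new* entries into the exposed class
    (``phi*chi*S0`` with ``S0 = Lambda/(beta+tau)``); V holds every other
    transfer, with outflows on the diagonal and inflows negative
    off-diagonal.
    """
    p = params
    if p.beta + p.tau == 0.0:
        raise DegenerateParameterError("DFE undefined: beta + tau is zero")
    S0 = p.Lambda / (p.beta + p.tau)
    F = np.zeros((4, 4))
    F[0, 1] = p.phi * p.chi * S0
    V = np.array([
        [p.sigma + p.tau, 0.0, 0.0, 0.0],
        [-p.Phi * p.sigma, p.tau + p.psi + p.alpha, 0.0, 0.0],
        [0.0, -(p.alpha + p.psi * (1.0 - p.omega)), p.upsilon + p.rho + p.tau, 0.0],
        [-(1.0 - p.Phi) * p.sigma, -p.psi * p.omega, -p.upsilon, p.tau + p.lam],
    ])
    return F, V


def compute_R0_ngm(params: ModelParameters) -> float:
    """Basic reproduction number as the spectral radius of F V^-1.

    Agrees with :func:`compute_R0` to within floating-point round-off;
    the closed form is the faster production path, this is the structural
    cross-check.
    """
    F, V = ngm_matrices(params)
    if np.linalg.det(V) == 0.0:
        raise DegenerateParameterError("transition matrix V is singular")
    K = F @ np.linalg.inv(V)
    return float(np.max(np.abs(np.linalg.eigvals(K))))


def dfe(params: ModelParameters) -> EquilibriumReport:
    """Addiction-free equilibrium, in closed form.

    The state is ``(Lambda/(beta+tau), 0, 0, 0, 0,
    beta*Lambda/((beta+tau)*tau))``: susceptibles balance recruitment
    against quitting and mortality, quitters balance the inflow beta*S
    against mortality.
    """
    p = params
    if p.beta + p.tau == 0.0:
        raise DegenerateParameterError("DFE undefined: beta + tau is zero")
    S0 = p.Lambda / (p.beta + p.tau)
    Q0 = p.beta * p.Lambda / ((p.beta + p.tau) * p.tau)
    state = StateVector(S0, 0.0, 0.0, 0.0, 0.0, Q0)
    residual = float(np.max(np.abs(rhs(state, params))))
    return EquilibriumReport(state=state, kind="DFE", residual=residual, admissible=True)


def eep(params: ModelParameters) -> EquilibriumReport | None:
    """Endemic equilibrium, or None when no admissible one exists (R0 <= 1).

    Solved by an algebraic cascade rather than by transcribing the
    multi-page rational closed forms:

    1. ``S* = (sigma+tau)*(tau+alpha+psi) / (sigma*phi*chi*Phi)`` — the
       susceptible level at which one addicted individual exactly
       replaces itself.
    2. At steady state I1, I2 and R are proportional to E
       (``I1 = c1*E`` etc. from their balance equations), so the
       remaining S-balance ``Lambda + zeta*lam*R = (phi*chi*I1 + beta
       + tau)*S*`` is *linear* in E and solves in closed form.
    3. ``Q = (beta*S* + (1-zeta)*lam*R)/tau`` feeds back into nothing and
       is recovered last.
    """
    p = params
    R0 = compute_R0(params)
    if R0 <= 1.0:
        return None
    S = (p.sigma + p.tau) * (p.tau + p.alpha + p.psi) / (p.sigma * p.phi * p.chi * p.Phi)
    c1 = p.Phi * p.sigma / (p.tau + p.psi + p.alpha)                       # I1 per unit E
    c2 = (p.alpha + p.psi * (1.0 - p.omega)) * c1 / (p.upsilon + p.rho + p.tau)  # I2 per unit E
    c3 = ((1.0 - p.Phi) * p.sigma + p.upsilon * c2 + p.psi * p.omega * c1) / (p.tau + p.lam)  # R per unit E
    slope = p.zeta * p.lam * c3 - p.phi * p.chi * c1 * S
    E = ((p.beta + p.tau) * S - p.Lambda) / slope
    I1, I2, R = c1 * E, c2 * E, c3 * E
    Q = (p.beta * S + (1.0 - p.zeta) * p.lam * R) / p.tau
    raw = np.array([S, E, I1, I2, R, Q])
    admissible = bool(np.all(raw > -ADMISSIBILITY_TOL))
    if not admissible:
        return None
    state = StateVector(*(float(x) for x in np.where(np.abs(raw) < ADMISSIBILITY_TOL, 0.0, raw)))
    residual = float(np.max(np.abs(rhs(state, params))))
    return EquilibriumReport(state=state, kind="EEP", residual=residual, admissible=True)


def strength_number(params: ModelParameters) -> float:
    """Second-order (strength) indicator ``-2*tau^2*phi*chi*Lambda/(tau+beta)``.

    Built from the second derivative of the incidence term at the DFE; it
    is nonpositive for any admissible parameters, indicating that the
    spread admits no renewal/resurgence process — a single wave that
    eventually dies out.
    """
    p = params
    return -2.0 * p.tau**2 * p.phi * p.chi * p.Lambda / (p.tau + p.beta)


def phi_star(params: ModelParameters) -> float:
    """Critical contact rate at which R0 crosses 1.

    ``phi* = (alpha+psi+tau)*(beta+tau)*(sigma+tau) / (Lambda*sigma*chi*Phi)``.
    R0 is linear in phi, so ``compute_R0(params.replace(phi=phi_star))``
    equals 1 exactly.
    """
    p = params
    denom = p.Lambda * p.sigma * p.chi * p.Phi
    if denom == 0.0:
        raise DegenerateParameterError("phi* undefined: Lambda*sigma*chi*Phi is zero")
    return (p.alpha + p.psi + p.tau) * (p.beta + p.tau) * (p.sigma + p.tau) / denom
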