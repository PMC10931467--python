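"""Core model definition: parameters, state, and the vector field.

The model tracks six compartments of a closed population exposed to
social-media addiction and its depressive sequelae:

``S``  susceptible (use social media casually or not at all, can be drawn in),
``E``  exposed (occasional users at risk of becoming addicted),
``I1`` addicted,
``I2`` depressed as a consequence of addiction,
``R``  recovered through treatment,
``Q``  permanent quitters.

Transmission is behavioural: susceptibles meet addicted individuals at
contact rate ``phi`` and convert with probability ``chi``, entering the
exposed class. A fraction ``Phi`` of those leaving ``E`` (at rate ``sigma``)
become addicted; the rest recover directly. Addicted individuals become
depressed through media impact (rate ``alpha``) or failed treatment
(rate ``(1-omega)*psi``); depressed individuals recover under treatment
(rate ``upsilon``) or die of depression (rate ``rho``). Recovered
individuals relapse to susceptibility (fraction ``zeta`` of the exit rate
``lam``) or quit permanently. Everyone is subject to natural mortality
``tau``; recruitment into ``S`` occurs at rate ``Lambda``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np

__all__ = [
    "ModelParameters",
    "StateVector",
    "PARAMETER_NAMES",
    "STATE_NAMES",
    "ParameterError",
    "InvalidInputError",
    "DegenerateParameterError",
    "NumericalError",
    "rhs",
    "total_population",
]


class ParameterError(ValueError):
    """A parameter set violates its admissibility constraints."""


class InvalidInputError(ValueError):
    """An input (state, name, file …) is malformed or non-finite."""


class DegenerateParameterError(ParameterError):
    """Parameters make a requested quantity undefined (zero denominator)."""


class NumericalError(RuntimeError):
    """A numerical routine failed (overflow, non-convergence …)."""


#: Canonical ASCII parameter names, in a fixed order used throughout.
PARAMETER_NAMES = (
    "Lambda", "zeta", "lam", "tau", "alpha", "beta", "chi",
    "upsilon", "sigma", "omega", "psi", "Phi", "rho", "phi",
)

#: Compartment names in state order.
STATE_NAMES = ("S", "E", "I1", "I2", "R", "Q")

# parameters constrained to [0, 1] (probabilities / fractions)
_UNIT_INTERVAL = frozenset({"zeta", "omega", "Phi", "chi"})


@dataclass(frozen=True)
class ModelParameters:
    """The fourteen nonnegative rates and fractions of the model.

    Parameters
    ----------
    Lambda : float
        Recruitment rate of susceptibles (individuals / time).
    zeta : float
        Fraction of recovered who become susceptible again (dimensionless,
        in [0, 1]); the remainder quit permanently.
    lam : float
        Rate of leaving the recovered class (1 / time).
    tau : float
        Natural death rate (1 / time); must be strictly positive.
    alpha : float
        Rate at which addiction induces depression via media impact (1 / time).
    beta : float
        Rate at which susceptibles quit social media outright (1 / time).
    chi : float
        Probability of transmission per contact (dimensionless, in [0, 1]).
    upsilon : float
        Recovery rate of depressed individuals under treatment (1 / time).
    sigma : float
        Rate of leaving the exposed class (1 / time).
    omega : float
        Probability that treatment of an addicted individual succeeds
        (dimensionless, in [0, 1]).
    psi : float
        Rate of leaving treatment (1 / time).
    Phi : float
        Fraction of exposed who become addicted (dimensionless, in [0, 1]).
    rho : float
        Depression-induced death rate (1 / time).
    phi : float
        Contact rate of susceptibles with addicted individuals (1 / time).
    """

    Lambda: float
    zeta: float
    lam: float
    tau: float
    alpha: float
    beta: float
    chi: float
    upsilon: float
    sigma: float
    omega: float
    psi: float
    Phi: float
    rho: float
    phi: float

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise ParameterError(f"parameter {name!r} must be a finite number, got {value!r}")
            object.__setattr__(self, name, float(value))
            if value < 0:
                raise ParameterError(f"parameter {name!r} must be nonnegative, got {value}")
            if name in _UNIT_INTERVAL and value > 1:
                raise ParameterError(f"parameter {name!r} is a fraction and must lie in [0, 1], got {value}")
        if self.tau <= 0:
            raise ParameterError(f"natural death rate tau must be > 0, got {self.tau}")

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        """Build from a flat name → value mapping; unknown keys are rejected."""
        unknown = set(mapping) - set(PARAMETER_NAMES)
        if unknown:
            raise InvalidInputError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = set(PARAMETER_NAMES) - set(mapping)
        if missing:
            raise InvalidInputError(f"missing parameter(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        unknown = set(changes) - set(PARAMETER_NAMES)
        if unknown:
            raise InvalidInputError(f"unknown parameter name(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)


class StateVector(NamedTuple):
    """Compartment sizes (individuals). Behaves as a plain 6-tuple."""

    S: float
    E: float
    I1: float
    I2: float
    R: float
    Q: float

    @classmethod
    def from_iterable(cls, values: Iterable[float]) -> "StateVector":
        vals = tuple(float(v) for v in values)
        if len(vals) != 6:
            raise InvalidInputError(f"state must have 6 components, got {len(vals)}")
        return cls(*vals)


def _as_state_array(state: Iterable[float]) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    if y.shape != (6,):
        raise InvalidInputError(f"state must be a 6-vector, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise InvalidInputError(f"state has non-finite components: {y}")
    return y


def rhs(state: Iterable[float], params: ModelParameters) -> np.ndarray:
    """Time derivative of the six compartments.

    Implements the coupled balance equations

    .. code-block:: text

        dS/dt  = Lambda + zeta*lam*R - phi*chi*I1*S - (beta + tau)*S
        dE/dt  = phi*chi*I1*S - (sigma + tau)*E
        dI1/dt = Phi*sigma*E - (tau + psi + alpha)*I1
        dI2/dt = (alpha + psi*(1 - omega))*I1 - (upsilon + rho + tau)*I2
        dR/dt  = (1 - Phi)*sigma*E + upsilon*I2 + psi*omega*I1 - (tau + lam)*R
        dQ/dt  = beta*S + (1 - zeta)*lam*R - tau*Q

    Every transfer appears with equal magnitude and opposite sign in its
    source and destination row, so summing the six rows leaves only
    recruitment and deaths: ``sum(rhs) = Lambda - tau*N - rho*I2``.

    Parameters
    ----------
    state : array-like of 6 floats
        Compartment sizes ``(S, E, I1, I2, R, Q)``. Admissibility
        (nonnegativity) is a caller responsibility; components are not
        clamped here.
    params : ModelParameters

    Returns
    -------
    numpy.ndarray
        The six derivatives, individuals / time.
    """
    y = _as_state_array(state)
    S, E, I1, I2, R, Q = y
    p = params
    infection = p.phi * p.chi * I1 * S
    return np.array([
        p.Lambda + p.zeta * p.lam * R - infection - (p.beta + p.tau) * S,
        infection - (p.sigma + p.tau) * E,
        p.Phi * p.sigma * E - (p.tau + p.psi + p.alpha) * I1,
        (p.alpha + p.psi * (1.0 - p.omega)) * I1 - (p.upsilon + p.rho + p.tau) * I2,
        (1.0 - p.Phi) * p.sigma * E + p.upsilon * I2 + p.psi * p.omega * I1 - (p.tau + p.lam) * R,
        p.beta * S + (1.0 - p.zeta) * p.lam * R - p.tau * Q,
    ])


def total_population(state: Iterable[float]) -> float:
    """Total population N = S + E + I1 + I2 + R + Q."""
    return float(_as_state_array(state).sum())
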