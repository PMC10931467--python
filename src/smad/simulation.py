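"""Fixed-step classical Runge–Kutta (RK-4) integration of the model.

A fixed step keeps runs bit-reproducible; the default step h = 0.001 is
the resolution used for the reference scenario runs, and trajectories
are thinned on storage (default every 100th step) so that a 500-time-unit
run stays small. Two dynamical invariants are monitored: positivity
(from nonnegative initial conditions no compartment should dip below
-1e-9) and boundedness (N(t) <= max(N(0), Lambda/tau) up to round-off,
since dN/dt = Lambda - tau*N - rho*I2 <= Lambda - tau*N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    InvalidInputError,
    ModelParameters,
    NumericalError,
    PARAMETER_NAMES,
    STATE_NAMES,
    StateVector,
    _as_state_array,
    rhs,
)

__all__ = [
    "Trajectory",
    "PositivityWarning",
    "rk4_step",
    "integrate",
    "detect_steady_state",
    "parameter_sweep",
]

#: tolerated undershoot before a stored component counts as a positivity violation
POSITIVITY_TOL = 1e-9


class PositivityWarning(UserWarning):
    """A stored trajectory component fell below -1e-9."""


@dataclass(frozen=True)
class Trajectory:
    """A uniformly-spaced (thinned) solution path.

    ``times[i]`` and ``states[i]`` are aligned; ``h`` is the integration
    step, ``thin`` the storage stride (``times`` are spaced ``h * thin``
    apart).
    """

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 6)
    params: ModelParameters
    h: float
    thin: int = 1
    positivity_violations: tuple = field(default=())

    @property
    def final_state(self) -> StateVector:
        return StateVector(*(float(v) for v in self.states[-1]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path) -> None:
        """Write as delimited text, full double precision."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _scalar_field(params: ModelParameters):
    """Close the vector field over plain floats for the tight RK-4 loop."""
    p = params
    L, zl, zl2 = p.Lambda, p.zeta * p.lam, (1.0 - p.zeta) * p.lam
    bt, st, tpa = p.beta + p.tau, p.sigma + p.tau, p.tau + p.psi + p.alpha
    urt, tl = p.upsilon + p.rho + p.tau, p.tau + p.lam
    pc, Ps, oS = p.phi * p.chi, p.Phi * p.sigma, (1.0 - p.Phi) * p.sigma
    aw, pw, be, up, ta = p.alpha + p.psi * (1.0 - p.omega), p.psi * p.omega, p.beta, p.upsilon, p.tau

    def f(S, E, I1, I2, R, Q):
        inc = pc * I1 * S
        return (L + zl * R - inc - bt * S,
                inc - st * E,
                Ps * E - tpa * I1,
                aw * I1 - urt * I2,
                oS * E + up * I2 + pw * I1 - tl * R,
                be * S + zl2 * R - ta * Q)

    return f


def _rk4_update(f, y, h):
    k1 = f(*y)
    k2 = f(*(yi + 0.5 * h * ki for yi, ki in zip(y, k1)))
    k3 = f(*(yi + 0.5 * h * ki for yi, ki in zip(y, k2)))
    k4 = f(*(yi + h * ki for yi, ki in zip(y, k3)))
    s = h / 6.0
    return tuple(yi + s * (a + 2.0 * b + 2.0 * c + d)
                 for yi, a, b, c, d in zip(y, k1, k2, k3, k4))


def rk4_step(state: Iterable[float], params: ModelParameters, h: float) -> StateVector:
    """One classical fourth-order Runge–Kutta update.

    Raises
    ------
    NumericalError
        If any intermediate or final component is non-finite.
    """
    if h <= 0:
        raise InvalidInputError(f"step size h must be > 0, got {h}")
    y = tuple(_as_state_array(state))
    out = _rk4_update(_scalar_field(params), y, h)
    if not all(np.isfinite(out)):
        raise NumericalError(f"non-finite state after RK-4 step: {out}")
    return StateVector(*(float(v) for v in out))


def integrate(
    params: ModelParameters,
    state0: Iterable[float],
    h: float = 0.001,
    t_end: float = 500.0,
    thin: int = 100,
) -> Trajectory:
    """Integrate the model on a uniform grid from t = 0 to t_end.

    Parameters
    ----------
    params, state0
        Model parameters and initial compartment sizes.
    h : float
        Integration step (time units).
    t_end : float
        Final time; the number of steps is ``round(t_end / h)``.
    thin : int
        Store every ``thin``-th step (the initial state is always stored,
        as is the final one).

    Returns
    -------
    Trajectory

    Warns
    -----
    PositivityWarning
        If any stored component drops below -1e-9.

    Raises
    ------
    NumericalError
        On overflow / non-finite state, reporting the offending time.
    """
    if h <= 0 or t_end <= 0:
        raise InvalidInputError(f"h and t_end must be > 0, got h={h}, t_end={t_end}")
    if thin < 1:
        raise InvalidInputError(f"thin must be >= 1, got {thin}")
    y = tuple(_as_state_array(state0))
    f = _scalar_field(params)
    n_steps = round(t_end / h)
    times = [0.0]
    states = [y]
    violations: list[tuple[float, str, float]] = []

    for i in range(1, n_steps + 1):
        y = _rk4_update(f, y, h)
        if i % thin == 0 or i == n_steps:
            if not all(np.isfinite(y)):
                raise NumericalError(f"non-finite state at t = {i * h:.6g}")
            t = i * h
            times.append(t)
            states.append(y)
            for name, comp in zip(STATE_NAMES, y):
                if comp < -POSITIVITY_TOL:
                    violations.append((t, name, comp))

    if violations:
        t0, name, comp = violations[0]
        warnings.warn(
            f"positivity violation: {name} = {comp:.3e} at t = {t0:.6g} "
            f"({len(violations)} stored-point violations in total)",
            PositivityWarning,
            stacklevel=2,
        )
    return Trajectory(
        times=np.array(times),
        states=np.array(states),
        params=params,
        h=h,
        thin=thin,
        positivity_violations=tuple(violations),
    )


def detect_steady_state(traj: Trajectory, tol: float = 1e-6, window: int = 10) -> StateVector | None:
    """Final state if the flow has stalled over the trailing window, else None.

    The criterion is on the vector field itself (max |dy/dt| < tol at each
    of the last ``window`` stored states), not on state differences, so it
    is insensitive to the storage stride.
    """
    if window < 1:
        raise InvalidInputError(f"window must be >= 1, got {window}")
    if len(traj.times) < window:
        return None
    for state in traj.states[-window:]:
        if float(np.max(np.abs(rhs(state, traj.params)))) >= tol:
            return None
    return traj.final_state


def parameter_sweep(
    base_params: ModelParameters,
    name: str,
    values: Sequence[float],
    state0: Iterable[float],
    h: float = 0.001,
    t_end: float = 500.0,
    thin: int = 100,
) -> list[Trajectory]:
    """Integrate once per value of a single parameter, all else fixed.

    Raises
    ------
    InvalidInputError
        If ``name`` is not a model parameter.
    """
    if name not in PARAMETER_NAMES:
        raise InvalidInputError(f"unknown parameter name {name!r}; expected one of {PARAMETER_NAMES}")
    return [
        integrate(base_params.replace(**{name: float(v)}), state0, h=h, t_end=t_end, thin=thin)
        for v in values
    ]
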