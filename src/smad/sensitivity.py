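"""Local and global sensitivity analysis of the reproduction number.

Local: the normalized forward sensitivity index (NFSI) of R0 with respect
to a parameter p is the elasticity (dR0/dp) * (p / R0). Because R0 is
multiplicatively separable in phi, chi and Phi (and Lambda), their
indices are exactly +1; the remaining parameters have simple rational
closed forms with a fixed sign pattern (sigma positive; beta, tau,
alpha, psi negative).

Global: parameters are perturbed jointly with a Latin hypercube design
(one draw per equal-probability stratum per parameter) and ranked; the
partial rank correlation coefficient (PRCC) of each parameter with a
model output is the correlation of the rank residuals after linearly
removing every other ranked parameter, with a t-test p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .equilibria import compute_R0
from .model import InvalidInputError, ModelParameters, STATE_NAMES
from .simulation import integrate

__all__ = [
    "NfsiReport",
    "LhsDesign",
    "PrccReport",
    "NFSI_NAMES",
    "nfsi_closed_form",
    "nfsi_numeric",
    "nfsi_table",
    "lhs_sample",
    "prcc",
    "run_prcc_experiment",
    "default_prcc_ranges",
]

#: parameters of R0 with a supported closed-form elasticity
NFSI_NAMES = ("Lambda", "sigma", "phi", "chi", "Phi", "beta", "tau", "alpha", "psi")

#: parameters bounded above by 1 (fractions); LHS ranges are clipped to respect this
_FRACTIONS = ("zeta", "omega", "Phi", "chi")


@dataclass(frozen=True)
class NfsiReport:
    """Per-parameter elasticities of R0 at a parameter point."""

    indices: dict[str, float]
    params: ModelParameters

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": list(self.indices), "nfsi": list(self.indices.values())}
        )


@dataclass(frozen=True)
class LhsDesign:
    """A Latin hypercube sample: one row per draw, one column per parameter."""

    samples: pd.DataFrame
    ranges: dict[str, tuple[float, float]]
    seed: int

    @property
    def n(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class PrccReport:
    """PRCC values and p-values of each design column against one output."""

    table: pd.DataFrame  # columns: parameter, prcc, p_value
    output: str
    n: int

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            row.parameter: {"prcc": row.prcc, "p_value": row.p_value}
            for row in self.table.itertuples()
        }


def nfsi_closed_form(params: ModelParameters, name: str) -> float:
    """Closed-form elasticity of R0 with respect to one parameter."""
    p = params
    if name in ("Lambda", "phi", "chi", "Phi"):
        return 1.0
    if name == "sigma":
        return p.tau / (p.tau + p.sigma)
    if name == "beta":
        return -p.beta / (p.beta + p.tau)
    if name == "alpha":
        return -p.alpha / (p.tau + p.alpha + p.psi)
    if name == "psi":
        return -p.psi / (p.tau + p.alpha + p.psi)
    if name == "tau":
        # -tau * d/dtau log[(alpha+psi+tau)(beta+tau)(sigma+tau)], expanded
        t = p.tau
        quad = (
            t**2
            + (2.0 / 3.0) * (p.psi + p.beta + p.alpha + p.sigma) * t
            + (1.0 / 3.0) * (p.psi + p.beta + p.alpha) * p.sigma
            + (1.0 / 3.0) * p.beta * (p.psi + p.alpha)
        )
        return -3.0 * t * quad / ((t + p.alpha + p.psi) * (p.beta + t) * (t + p.sigma))
    raise InvalidInputError(f"no closed-form NFSI for {name!r}; expected one of {NFSI_NAMES}")


def nfsi_numeric(params: ModelParameters, name: str, rel_step: float = 1e-6) -> float:
    """Central-difference elasticity (dR0/dp) * (p / R0).

    Raises
    ------
    InvalidInputError
        If the parameter value is zero (elasticity undefined at 0) or R0
        vanishes at the base point.
    """
    if name not in NFSI_NAMES:
        raise InvalidInputError(f"NFSI not defined for {name!r}; expected one of {NFSI_NAMES}")
    value = getattr(params, name)
    if value <= 0:
        raise InvalidInputError(f"numeric NFSI needs {name!r} > 0, got {value}")
    base = compute_R0(params)
    if base == 0.0:
        raise InvalidInputError("elasticity undefined: R0 = 0 at the base point")
    step = rel_step * value
    hi = compute_R0(params.replace(**{name: value + step}))
    lo = compute_R0(params.replace(**{name: value - step}))
    return (hi - lo) / (2.0 * step) * value / base


def nfsi_table(params: ModelParameters, names: Sequence[str] = NFSI_NAMES) -> NfsiReport:
    """Closed-form NFSI for each requested parameter."""
    return NfsiReport(
        indices={name: nfsi_closed_form(params, name) for name in names},
        params=params,
    )


def lhs_sample(ranges: Mapping[str, tuple[float, float]], n: int, seed: int) -> LhsDesign:
    """Stratified uniform Latin hypercube design.

    Each column partitions its range into ``n`` equal strata with exactly
    one draw per stratum; identical seeds give identical designs.
    """
    if n < 2:
        raise InvalidInputError(f"LHS needs n >= 2, got {n}")
    names = list(ranges)
    lows = np.array([ranges[k][0] for k in names], dtype=float)
    highs = np.array([ranges[k][1] for k in names], dtype=float)
    if np.any(lows >= highs):
        bad = [k for k in names if ranges[k][0] >= ranges[k][1]]
        raise InvalidInputError(f"invalid range(s) (lower >= upper): {bad}")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    scaled = qmc.scale(unit, lows, highs)
    return LhsDesign(samples=pd.DataFrame(scaled, columns=names), ranges=dict(ranges), seed=seed)


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=0)


def prcc(design: LhsDesign | pd.DataFrame, output_values: Iterable[float], output: str = "output") -> PrccReport:
    """Partial rank correlation of each design column with the output.

    For column j: rank-transform everything, regress both rank(x_j) and
    rank(y) on the remaining ranked columns (with intercept), and
    correlate the two residual vectors. The p-value uses the t statistic
    with n - 2 - (p - 1) degrees of freedom, p being the number of
    design columns.

    Raises
    ------
    InvalidInputError
        On too few rows, non-finite outputs, or a constant column.
    """
    X = design.samples if isinstance(design, LhsDesign) else pd.DataFrame(design)
    y = np.asarray(list(output_values), dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise InvalidInputError(f"output length {len(y)} != design rows {n}")
    if n <= p + 2:
        raise InvalidInputError(f"PRCC needs n > p + 2 rows (n={n}, p={p})")
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("output contains non-finite values")

    ranks = _rank(X.to_numpy())
    y_rank = _rank(y)
    df_resid = n - 2 - (p - 1)
    rows = []
    for j, name in enumerate(X.columns):
        if np.ptp(X.iloc[:, j].to_numpy()) == 0.0:
            raise InvalidInputError(f"design column {name!r} is constant; PRCC undefined")
        others = np.column_stack([np.ones(n), np.delete(ranks, j, axis=1)])
        beta_x, *_ = np.linalg.lstsq(others, ranks[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, y_rank, rcond=None)
        rx = ranks[:, j] - others @ beta_x
        ry = y_rank - others @ beta_y
        denom = np.linalg.norm(rx) * np.linalg.norm(ry)
        r = float(rx @ ry / denom) if denom > 0 else 0.0
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) >= 1.0:
            p_value = 0.0
        else:
            t_stat = r * np.sqrt(df_resid / (1.0 - r * r))
            p_value = float(2.0 * stats.t.sf(abs(t_stat), df_resid))
        rows.append({"parameter": name, "prcc": r, "p_value": p_value})
    return PrccReport(table=pd.DataFrame(rows), output=output, n=n)


def default_prcc_ranges(
    baseline: ModelParameters,
    names: Sequence[str] = NFSI_NAMES,
    rel_width: float = 0.25,
) -> dict[str, tuple[float, float]]:
    """Symmetric +-25% ranges around the baseline, clipped to admissibility.

    Fractions are capped at 1; lower bounds never go below 0 (and tau,
    which must stay positive, is bounded away from 0 by the relative
    width itself since its baseline is positive).
    """
    ranges = {}
    for name in names:
        center = getattr(baseline, name)
        if center <= 0:
            raise InvalidInputError(f"cannot build a perturbation range around {name!r} = {center}")
        lo = center * (1.0 - rel_width)
        hi = center * (1.0 + rel_width)
        if name in _FRACTIONS:
            hi = min(hi, 1.0)
        ranges[name] = (lo, hi)
    return ranges


def run_prcc_experiment(
    baseline: ModelParameters,
    n: int = 5000,
    seed: int = 0,
    outputs: Sequence[str] = ("R0",),
    ranges: Mapping[str, tuple[float, float]] | None = None,
    t_eval: float = 50.0,
    h: float = 0.01,
    state0: Sequence[float] = (100.0, 1.0, 5.0, 2.0, 0.0, 10.0),
) -> dict[str, PrccReport]:
    """LHS-and-PRCC study of R0 and/or compartment sizes at a fixed time.

    Compartment outputs are read from an RK-4 trajectory at ``t_eval``;
    the R0 output is evaluated directly from the closed form (fast, so
    the reference design size n = 5000 runs in seconds).

    Returns one :class:`PrccReport` per requested output. Each report
    carries the design size; the caller-supplied seed makes the whole
    experiment reproducible.
    """
    valid_outputs = ("R0",) + STATE_NAMES
    for out in outputs:
        if out not in valid_outputs:
            raise InvalidInputError(f"unknown output {out!r}; expected one of {valid_outputs}")
    if ranges is None:
        ranges = default_prcc_ranges(baseline)
    design = lhs_sample(ranges, n, seed)

    needs_trajectory = [o for o in outputs if o != "R0"]
    reports: dict[str, PrccReport] = {}
    param_sets = [
        baseline.replace(**{k: float(v) for k, v in row.items()})
        for row in design.samples.to_dict(orient="records")
    ]
    if "R0" in outputs:
        values = [compute_R0(ps) for ps in param_sets]
        reports["R0"] = prcc(design, values, output="R0")
    if needs_trajectory:
        finals = np.empty((n, 6))
        for i, ps in enumerate(param_sets):
            traj = integrate(ps, state0, h=h, t_end=t_eval, thin=max(1, round(t_eval / h) // 10))
            finals[i] = traj.states[-1]
        for out in needs_trajectory:
            idx = STATE_NAMES.index(out)
            reports[out] = prcc(design, finals[:, idx], output=f"{out}@t={t_eval:g}")
    return reports
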