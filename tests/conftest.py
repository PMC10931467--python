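import numpy as np
import pytest

import smad


@pytest.fixture(scope="session")
def case1_params():
    """Subthreshold reference parameter set (R0 ≈ 0.8684)."""
    return smad.load_scenario("case1_r0_lt_1").params


@pytest.fixture(scope="session")
def case2_params():
    """Supercritical reference parameter set (R0 ≈ 1.3372)."""
    return smad.load_scenario("case2_r0_gt_1").params


@pytest.fixture(scope="session")
def baseline_params():
    return smad.load_scenario("table1_baseline").params


@pytest.fixture(scope="session")
def reference_ic():
    return smad.StateVector(100.0, 1.0, 5.0, 2.0, 0.0, 10.0)


@pytest.fixture(scope="session")
def case1_traj(case1_params, reference_ic):
    """Full-resolution reference run of the subthreshold scenario."""
    return smad.integrate(case1_params, reference_ic, h=0.001, t_end=500.0, thin=100)


@pytest.fixture(scope="session")
def case2_traj(case2_params, reference_ic):
    """Full-resolution reference run of the supercritical scenario."""
    return smad.integrate(case2_params, reference_ic, h=0.001, t_end=500.0, thin=100)


# Plausible draw ranges for each parameter, loosely around the baseline
# table (ranged entries widened). Used for randomized property checks.
_DRAW_RANGES = {
    "Lambda": (0.1, 1.0),
    "zeta": (0.05, 0.95),
    "lam": (0.05, 1.0),
    "tau": (0.05, 0.25),
    "alpha": (0.3, 0.5),
    "beta": (0.001, 0.1),
    "chi": (0.05, 1.0),
    "upsilon": (0.1, 1.0),
    "sigma": (0.05, 1.0),
    "omega": (0.05, 0.95),
    "psi": (0.001, 0.1),
    "Phi": (0.1, 1.0),
    "rho": (0.001, 0.1),
    "phi": (0.1, 0.8),
}


def draw_params(rng: np.random.Generator) -> smad.ModelParameters:
    """One random admissible parameter set from the draw ranges."""
    return smad.ModelParameters(
        **{name: float(rng.uniform(lo, hi)) for name, (lo, hi) in _DRAW_RANGES.items()}
    )


def draw_state(rng: np.random.Generator, scale: float = 5.0) -> np.ndarray:
    return rng.uniform(0.0, scale, size=6)
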