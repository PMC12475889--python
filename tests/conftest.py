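"""Shared fixtures: scenario grid and representative simulated cohorts."""

import numpy as np
import pytest

from switchmsm import ScenarioConfig, load_scenarios, simulate_cohort

# Fixed base seed for every stochastic test in the suite.
SEED = 1729


@pytest.fixture(scope="session")
def scenarios():
    """The packaged 22-scenario grid with the suite's base seed."""
    return load_scenarios(seed=SEED)


@pytest.fixture(scope="session")
def cohort1(scenarios):
    """One scenario-1 cohort (constant hazard, many events)."""
    return simulate_cohort(scenarios[1], 0)


@pytest.fixture(scope="session")
def cohort2(scenarios):
    """One scenario-2 cohort (strongly decreasing Weibull hazard)."""
    return simulate_cohort(scenarios[2], 0)


@pytest.fixture()
def small_config():
    """A fast scenario for replicate-heavy checks (500 + 500 subjects)."""
    return ScenarioConfig(
        scenario_id=90,
        shape=1.0,
        scale=10.0,
        switch_time=1.0,
        switch_prop=0.3,
        n_td=500,
        n_cd=500,
        admin_censor=8.0,
        n_reps=50,
        seed=SEED,
    )


def binom_band(p: float, n: int, z: float) -> tuple[float, float]:
    """Symmetric normal-approximation band around a binomial proportion."""
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
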