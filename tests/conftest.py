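import numpy as np
import pandas as pd
import pytest

from srbmix import (
    apply_window_rules,
    default_vietnam_like_scenario,
    fit,
    impute_sampling_error,
    short_config,
    simulate_database,
)
from srbmix.model import AR1Params, TrapezoidParams
from srbmix.synthetic import ScenarioSpec, SourcePlan

REFERENCE_SEED = 3


@pytest.fixture(scope="session")
def default_scenario():
    return default_vietnam_like_scenario(seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def reference_obs(default_scenario):
    """Preprocessed observations from the reference synthetic scenario."""
    _, obs = simulate_database(default_scenario, seed=REFERENCE_SEED)
    return impute_sampling_error(apply_window_rules(obs))


@pytest.fixture(scope="session")
def reference_fit(reference_obs):
    """Shortened-chain fit of the reference scenario, shared across tests."""
    return fit(reference_obs, short_config(), seed=1)


def two_region_scenario(
    xi_a=0.08,
    xi_b=0.0,
    births=5000,
    every=1,
    seed=0,
    year_start=1985,
    year_end=2016,
    sigma_eps=0.005,
):
    """A compact two-region scenario: region A transitions, region B does not."""
    trap_a = TrapezoidParams(2000.0, 10.0, 4.0, 14.0, xi_a)
    trap_b = TrapezoidParams(2000.0, 10.0, 4.0, 14.0, xi_b)
    years = tuple(range(year_start, year_end + 1, every))
    return ScenarioSpec(
        regions=("RRD", "MKD"),
        year_start=year_start,
        year_end=year_end,
        trapezoids={"RRD": trap_a, "MKD": trap_b},
        delta={"RRD": 1 if xi_a > 0 else 0, "MKD": 1 if xi_b > 0 else 0},
        ar1=AR1Params(rho=0.5, sigma_eps=sigma_eps),
        baseline=1.063,
        sources=(
            SourcePlan(
                name="Annual registry",
                source_type="census",
                survey_year=year_end,
                years=years,
                births_per_region_year=births,
            ),
        ),
        seed=seed,
    )
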