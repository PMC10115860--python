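import numpy as np
import pandas as pd
import pytest

from stormlag.exposure import filter_exposed
from stormlag.matching import LAG_COLUMNS, build_matched_sets, build_model_table
from stormlag.synthetic import ScenarioConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    """A fast 10-ZCTA scenario with nonzero lag effects and nuisance terms."""
    return ScenarioConfig(
        n_zctas=10,
        year_start=2000,
        year_end=2011,
        storms_per_year=0.3,
        true_lag_betas=(0.0, 0.2, 0.1, 0.0, 0.3, 0.2, 0.1, 0.0, 0.0, 0.0),
        random_intercept_sd=0.1,
        year_effects=tuple([0.0] + [0.02 * i for i in range(1, 12)]),
        seed=42,
        subgroup_resolution=True,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return simulate_dataset(small_scenario)


@pytest.fixture(scope="session")
def small_matched(small_scenario, small_dataset):
    events = filter_exposed(small_dataset.storm_events)
    sets, report = build_matched_sets(
        events, small_scenario.years, rng=np.random.default_rng(7)
    )
    return sets, report


@pytest.fixture(scope="session")
def small_table(small_matched, small_dataset) -> pd.DataFrame:
    sets, _ = small_matched
    return build_model_table(sets, small_dataset.counts, small_dataset.denominators)


def make_two_group_table(
    counts_exposed,
    offsets_exposed,
    counts_control,
    offsets_control,
    zcta="Z0",
) -> pd.DataFrame:
    """Minimal model table with a single active indicator (lag 0).

    Used for closed-form Poisson MLE checks: exposed rows carry lag_0 = 1,
    control rows carry all-zero indicators.
    """
    n_e, n_c = len(counts_exposed), len(counts_control)
    rows = {
        "set_id": [f"{zcta}:S"] * (n_e + n_c),
        "zcta_id": [zcta] * (n_e + n_c),
        "storm_id": ["S"] * (n_e + n_c),
        "date": pd.date_range("2005-06-01", periods=n_e + n_c),
        "role": ["exposed"] * n_e + ["control"] * n_c,
        "lag": [0] * (n_e + n_c),
        "count": list(counts_exposed) + list(counts_control),
        "log_denom": list(np.log(offsets_exposed)) + list(np.log(offsets_control)),
    }
    df = pd.DataFrame(rows)
    for col in LAG_COLUMNS:
        df[col] = 0
    df.loc[df["role"] == "exposed", "lag_0"] = 1
    df["year"] = df["date"].dt.year
    df["dow"] = df["date"].dt.dayofweek
    df["exposed_flag"] = (df["role"] == "exposed").astype(int)
    return df
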