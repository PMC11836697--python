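import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nestphen.decomposition import centre
from nestphen.phenology_core import build_female_seasons
from nestphen.synthetic_data import SimulationParams, simulate
from nestphen.window_search import WindowSpec, annual_window_means

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A down-scaled population (≈500 events) for fast structural tests."""
    return SimulationParams(n_years=14, recruits_year1=12.0, recruitment_growth=1.05)


@pytest.fixture(scope="session")
def small_sim(small_params):
    return simulate(small_params, seed=11)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size simulated study (31 years, defaults)."""
    return simulate(SimulationParams(), seed=11)


@pytest.fixture(scope="session")
def default_design(default_sim):
    events, sst, _ = default_sim
    seasons = build_female_seasons(events)
    annual = annual_window_means(sst, WindowSpec(88, 119))
    return centre(seasons, {int(y): float(v) for y, v in annual.items()})


def make_crossed_panel(seed: int = 42) -> pd.DataFrame:
    """Small unbalanced panel with known structure for mixed-model tests.

    40 females observed in 1–4 seasons of 2000–2009; fnd = 160 − 0.7·(year −
    2000) + female intercept (sd 6) + residual (sd 5). Deterministic given
    the seed; seed 42 is the dataset behind the frozen lme4 oracle values.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(40):
        n_seasons = rng.integers(1, 5)
        years = np.sort(rng.choice(np.arange(2000, 2010), size=n_seasons, replace=False))
        u = rng.normal(0, 6)
        for y in years:
            rows.append((f"F{i:03d}", int(y), 160 - 0.7 * (y - 2000) + u + rng.normal(0, 5)))
    df = pd.DataFrame(rows, columns=["female_id", "year", "fnd"])
    mean_t = df.groupby("female_id")["year"].transform("mean")
    grand = mean_t.groupby(df["female_id"]).first().mean()
    df["d_t"] = df["year"] - mean_t
    df["mean_t"] = mean_t - grand
    return df
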