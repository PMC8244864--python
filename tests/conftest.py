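"""Shared fixtures: small synthetic studies generated at test time."""

import warnings

import pytest

from nestdecay.core import compute_ages
from nestdecay.simulate import (ClimateSimConfig, CohortSimConfig,
                                simulate_climate, simulate_cohort)

warnings.filterwarnings("ignore", message="ArviZ is undergoing")


@pytest.fixture(scope="session")
def daily_climate():
    """Two years of synthetic daily climate (with planted-storm truth)."""
    return simulate_climate(ClimateSimConfig(seed=101))


@pytest.fixture(scope="session")
def small_cohort():
    """A ~330-nest cohort with truth: (records, design, ages, truth)."""
    records, design, truth = simulate_cohort(CohortSimConfig(n_groups=40,
                                                             seed=42))
    return records, design, compute_ages(records), truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A quick two-chain fit of a reduced model on the small cohort."""
    from nestdecay.survival import ModelSpec, sample_posterior

    _, design, ages, _ = small_cohort
    spec = ModelSpec(factors=("C", "E", "S"))
    draws = sample_posterior(spec, design, ages, chains=2, iterations=800,
                             warmup=400, seed=7, check_rhat=False)
    return spec, draws


@pytest.fixture(scope="session")
def survey_ages():
    """Ages from a single-survey style study: 12 months of monitoring,
    marking confined to the first six months (the setting where fixed
    revisit offsets are meaningful)."""
    import datetime as dt

    cfg = CohortSimConfig(n_groups=47, nests_per_group_mean=9.6,
                          start=dt.date(2016, 7, 1), end=dt.date(2017, 6, 30),
                          marking_end=dt.date(2016, 12, 31), seed=11)
    records, design, truth = simulate_cohort(cfg)
    return compute_ages(records), truth
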