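from __future__ import annotations

import numpy as np
import pytest

from readgain import CohortConfig, GroupTruth, SegmentCalendar, generate_cohort
from readgain import reference


@pytest.fixture(scope="session")
def cal() -> SegmentCalendar:
    return SegmentCalendar()


@pytest.fixture(scope="session")
def zero_noise_cohort(cal):
    """Full-size cohort from the published reading-frequency truths, no noise."""
    cfg = CohortConfig(noise_sd=0.0, seed=7)
    return generate_cohort(cfg, cal)


@pytest.fixture(scope="session")
def zero_noise_ses_cohort(cal):
    """Full-size cohort from the published socioeconomic-group truths, no noise."""
    from readgain.cohort import default_ses_groups

    cfg = CohortConfig(
        n_children=3374,
        groups=default_ses_groups(),
        label_kind="ses",
        noise_sd=0.0,
        seed=7,
    )
    return generate_cohort(cfg, cal)


@pytest.fixture(scope="session")
def single_group_cfg():
    """One homogeneous group with the published all-sample coefficients."""
    beta = reference.beta_per_day("all")

    def make(n=400, noise_sd=0.0, seed=0, **kw):
        return CohortConfig(
            n_children=n,
            groups={"every day": GroupTruth(beta=beta, count=n)},
            noise_sd=noise_sd,
            seed=seed,
            **kw,
        )

    return make


@pytest.fixture(scope="session")
def calibrated_cohort(cal, single_group_cfg):
    """Full-size noisy cohort calibrated to the published standard errors."""
    return generate_cohort(single_group_cfg(n=3657, noise_sd=13.0, seed=20260923), cal)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
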