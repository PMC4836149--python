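"""Shared fixtures: desk-scale pipeline configurations and small cohorts.

The end-to-end tests run the full nested-CV pipeline at reduced — but
statistically honest — problem sizes: 10 stability subsamples over a
20-value lambda grid down to 0.1*lambda_max, and a 4x4 (C, sigma^2) SVM
grid with the full 10-fold inner CV.  The cohort conditions themselves
(group sizes, effect sizes, seeds) are never reduced.
"""

import numpy as np
import pytest

from mciconv import StabilityConfig, SVMConfig, SynthConfig, generate_cohort


def desk_stability(**overrides) -> StabilityConfig:
    base = dict(n_subsamples=10, n_lambdas=20, lambda_min_ratio=0.1)
    base.update(overrides)
    return StabilityConfig(**base)


def desk_svm(n_features: int = 10, **overrides) -> SVMConfig:
    base = dict(
        C_grid=2.0 ** np.arange(-3, 8, 3),
        sigma2_grid=2.0 ** np.arange(-7, 4, 3) * n_features,
    )
    base.update(overrides)
    return SVMConfig(**base)


@pytest.fixture(scope="session")
def stability_cfg() -> StabilityConfig:
    return desk_stability()


@pytest.fixture(scope="session")
def svm_cfg() -> SVMConfig:
    return desk_svm()


@pytest.fixture(scope="session")
def small_cohort():
    """12/12 cohort with a strong injected effect; fast end-to-end material."""
    return generate_cohort(
        SynthConfig(n_mcinc=12, n_mcic=12, effect_size_ct=0.5, seed=42)
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Two groups drawn from one distribution (no effect)."""
    cohort, _ = generate_cohort(
        SynthConfig(n_mcinc=12, n_mcic=12, effect_size_ct=0.0, seed=43)
    )
    return cohort
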