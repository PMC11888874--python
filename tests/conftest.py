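from __future__ import annotations

import numpy as np
import pytest

from cpetwave.classify import KernelSpec
from cpetwave.evaluate import CVConfig, cross_validate
from cpetwave.features import FeatureConfig, Layout, build_feature_matrix
from cpetwave.records import Condition
from cpetwave.synthetic import SyntheticConfig, generate_cohort


def mw3_linear_cv(delta: float, seed: int) -> tuple[float, float]:
    """5x5-fold CV of the linear-kernel MW3 pipeline on one synthetic
    45-subject cohort; returns (macro accuracy %, macro recall %)."""
    cohort = generate_cohort(SyntheticConfig(n_per_class=15, delta=delta, seed=seed))
    fm = build_feature_matrix(cohort, FeatureConfig(layout=Layout.MW3))
    report = cross_validate(fm, KernelSpec(), CVConfig(k=5, repeats=5, seed=seed))
    return report.macro.accuracy, report.macro.recall


@pytest.fixture(scope="session")
def mw3_delta_sweep() -> dict[float, tuple[float, float]]:
    """20-seed averages of (macro accuracy, macro recall) for the linear
    MW3 pipeline at each separation delta.  Shared by the separability
    property test and the acceptance suite."""
    seeds = range(20)
    sweep = {}
    for delta in (0.0, 1.0, 2.0, 4.0):
        results = np.array([mw3_linear_cv(delta, seed) for seed in seeds])
        sweep[delta] = (float(results[:, 0].mean()), float(results[:, 1].mean()))
    return sweep


@pytest.fixture
def binary_cohort():
    cfg = SyntheticConfig(
        n_per_class=15, classes=(Condition.HF, Condition.MS), delta=2.0, seed=7
    )
    return generate_cohort(cfg)


@pytest.fixture
def multi_cohort():
    cfg = SyntheticConfig(n_per_class=15, delta=2.0, seed=7)
    return generate_cohort(cfg)
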