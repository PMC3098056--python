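import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import peakbn as pb

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One draw from the canonical synthetic study conditions."""
    table, truth = pb.generate(pb.default_spec(seed=1))
    return table, truth


@pytest.fixture(scope="session")
def stability_run(default_dataset):
    """Repeated stratified 10-fold CV on the canonical synthetic table.

    25 repeats (250 networks) instead of 100 keep the suite fast; every
    threshold of the protocol (multiplier 3.2, drop 0.75, n_perm 100) is at
    its default value.
    """
    table, truth = default_dataset
    report = pb.run_cv(table, pb.CVPlan(k=10, n_repeats=25, seed=7))
    return table, truth, report


@pytest.fixture()
def small_table():
    """Tiny two-class table with one clearly diagnostic feature."""
    rng = np.random.default_rng(42)
    n = 60
    labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    x0 = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(3, 1, n // 2)])
    x1 = rng.normal(5, 2, n)
    return pb.SampleTable(
        case_ids=np.array([f"c{i}" for i in range(n)]),
        class_labels=labels,
        feature_ids=np.array([1000.0, 2000.0]),
        abundances=np.column_stack([x0, x1]),
    )
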