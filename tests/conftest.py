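import numpy as np
import pytest

import nirsdetect as nd


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: strong effect, complete scan schedule."""
    return nd.CohortConfig(n_participants=36, scan_minutes=4, sample_rate=5,
                           effect_size=2.5, scan_missing_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ds, cohort = nd.build_dataset(small_config)
    nd.attach_labels(ds, cohort)
    return ds, cohort


@pytest.fixture(scope="session")
def cv_result(small_dataset):
    ds, _ = small_dataset
    spec = nd.DetachKernelModel(n_kernels=300, prune_fraction=0.15,
                                min_fraction=0.2)
    return nd.evaluate_cohort(ds, spec, seed=5)


@pytest.fixture(scope="session")
def structural_cohort():
    """Study-scale cohort without signal matrices (structure only)."""
    return nd.generate_cohort(nd.CohortConfig(seed=42), include_signals=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
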