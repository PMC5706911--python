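import pytest

from ctlnc.config import CohortSpec
from ctlnc import simulate as sim


@pytest.fixture(scope="session")
def small_spec():
    """Fast cohort used by most unit tests."""
    return CohortSpec(
        n_genes=300,
        n_lncrna=120,
        n_tumor_samples_per_type=60,
        n_normal_individuals=3,
        cancer_types=("CANCER_A", "CANCER_B"),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return sim.build_truth(small_spec)


@pytest.fixture(scope="session")
def small_panel(small_spec, small_truth):
    panel, _ = sim.generate_normal_panel(small_spec, small_truth)
    return panel


@pytest.fixture(scope="session")
def small_cohorts(small_spec, small_truth):
    return sim.generate_tumor_cohorts(small_spec, small_truth)


@pytest.fixture(scope="session")
def small_annotation(small_spec, small_truth, small_cohorts):
    # tumor generation must run first so activated_samples is populated
    return sim.generate_annotation(small_spec, small_truth)
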