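import pytest

from plateletome.quantify import ExpressionMatrix, normalize_and_call, quantify_samples
from plateletome.simulate import CohortConfig, make_genome, simulate_read_sets


@pytest.fixture(scope="session")
def cohort_cfg():
    return CohortConfig(seed=101)


@pytest.fixture(scope="session")
def cohort_bundle(cohort_cfg):
    return make_genome(cohort_cfg)


@pytest.fixture(scope="session")
def cohort_reads(cohort_cfg, cohort_bundle):
    return simulate_read_sets(cohort_bundle, cohort_cfg)


@pytest.fixture(scope="session")
def cohort_quantified(cohort_cfg, cohort_bundle, cohort_reads):
    """(expression matrix, breakdown table, feature->category map) for the default cohort."""
    rpkm, breakdown, feature_category = quantify_samples(cohort_reads, cohort_bundle)
    matrix = normalize_and_call(ExpressionMatrix(values=rpkm))
    return matrix, breakdown, feature_category
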