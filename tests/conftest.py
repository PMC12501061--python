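import warnings

import numpy as np
import pytest

from coexsig import preprocess
from coexsig.synthetic import SimulationParams, generate_dataset

#: Compact cohort for unit tests: two 60-gene blocks in 500 genes, 160
#: samples — small enough to run in seconds, structured enough for every
#: stage of the pipeline to have something to find.
SMALL_PARAMS = SimulationParams(
    n_samples=160, n_genes=500, module_sizes=(60, 60), seed=7
)


@pytest.fixture(scope="session")
def small_dataset():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    """(raw_filtered, log2_cleaned, clinical, traits, truth) for the
    compact cohort, sharing one preprocessing run across tests."""
    expr, clinical, truth = small_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = preprocess.filter_missing_transcripts(expr)
        raw, clinical = preprocess.clean_clinical_samples(raw, clinical)
        log2 = preprocess.log2_transform(raw)
        log2, removed = preprocess.remove_outlier_samples(log2)
        if removed:
            clinical = clinical.subset(log2.sample_ids)
            raw = raw.subset_samples(log2.sample_ids)
        log2 = preprocess.regress_covariates(log2, clinical)
        traits = preprocess.encode_traits(clinical)
    return raw, log2, clinical, traits, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
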