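import numpy as np
import pandas as pd
import pytest

from mirlung.data_model import Cohort, CtMatrix, SampleTable


def make_cohort(values, phenotype, sex=None, subject_ids=None,
                phenotype_name="fev1_fvc"):
    """Build a small aligned cohort from raw arrays."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    feature_ids = [f"miR-{i:03d}" for i in range(n_feat)]
    sample_ids = [f"S{j:03d}" for j in range(n_samp)]
    if subject_ids is None:
        subject_ids = sample_ids
    if sex is None:
        sex = ["male" if j % 2 == 0 else "female" for j in range(n_samp)]
    table = SampleTable(pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": subject_ids,
        "sex": sex,
        phenotype_name: np.asarray(phenotype, dtype=float),
    }))
    return Cohort(CtMatrix(feature_ids, sample_ids, values), table)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_cohort(rng):
    """8 features x 30 samples of pure noise."""
    values = 24 + rng.standard_normal((8, 30))
    phenotype = 78 + 8 * rng.standard_normal(30)
    return make_cohort(values, phenotype)
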