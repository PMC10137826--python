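import numpy as np
import pandas as pd
import pytest

from mirpair import COPD, HEALTHY, ExpressionCohort, PairMatrix


def make_cohort(
    values, features=None, samples=None, labels=None, scale="expression", cohort_id="toy"
) -> ExpressionCohort:
    """Build a small cohort from a nested list / array."""
    arr = np.asarray(values, dtype=float)
    n_feat, n_samp = arr.shape
    features = features or [f"miR-{i + 1:03d}" for i in range(n_feat)]
    samples = samples or [f"S{i + 1}" for i in range(n_samp)]
    if labels is None:
        half = n_samp // 2
        labels = [COPD] * half + [HEALTHY] * (n_samp - half)
    return ExpressionCohort(
        cohort_id=cohort_id,
        values=pd.DataFrame(arr, index=features, columns=samples),
        labels=pd.Series(labels, index=samples),
        scale=scale,
    )


def make_pair_matrix(scores, pairs=None, samples=None, labels=None) -> PairMatrix:
    arr = np.asarray(scores, dtype=int)
    n_pairs, n_samp = arr.shape
    pairs = pairs or [f"miR-{2 * i + 1:03d}|miR-{2 * i + 2:03d}" for i in range(n_pairs)]
    samples = samples or [f"S{i + 1}" for i in range(n_samp)]
    if labels is None:
        half = n_samp // 2
        labels = [COPD] * half + [HEALTHY] * (n_samp - half)
    return PairMatrix(
        scores=pd.DataFrame(arr, index=pairs, columns=samples),
        labels=pd.Series(labels, index=samples),
    )


@pytest.fixture
def random_cohort():
    """10 features x 20 samples of continuous values, balanced labels."""
    rng = np.random.default_rng(42)
    return make_cohort(rng.normal(5, 2, size=(10, 20)))
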