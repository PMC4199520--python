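import numpy as np
import pytest

from faimsvoc import (
    IonCurrentMatrix,
    MatrixPair,
    FaimsSample,
    PipelineConfig,
    SyntheticConfig,
    generate_cohort,
)

#: Reduced grid used throughout the suite: keeps the LOO studies fast while
#: preserving the blob-on-background structure of the generator.
SMALL_GRID = dict(n_df=16, n_cv=64)


def make_matrix(current, polarity="positive"):
    current = np.asarray(current, dtype=float)
    n_df, n_cv = current.shape
    return IonCurrentMatrix(polarity, np.arange(n_df, dtype=float),
                            np.arange(n_cv, dtype=float), current)


def make_pair(pos, neg=None):
    neg = pos if neg is None else neg
    return MatrixPair(make_matrix(pos, "positive"), make_matrix(neg, "negative"))


def make_sample(pid, label, replicate_grids, **kw):
    return FaimsSample(pid, label, [make_pair(g) for g in replicate_grids], **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """16-patient cohort with a strong planted signal on the reduced grid."""
    cfg = SyntheticConfig(n_cd=8, n_ibs=8, effect_size=2.0, seed=7, **SMALL_GRID)
    return generate_cohort(cfg)


@pytest.fixture
def default_pipeline():
    return PipelineConfig()
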