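import numpy as np
import pytest

from selv.core import FrequencyRecord, build_locus_table
from selv.io import LabeledVariant


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def mito_records():
    """A tiny helixMTdb-style resource on the mitochondrial contig."""
    return [
        FrequencyRecord("chrM", 152, "T", "C", 0.3),
        FrequencyRecord("chrM", 152, "T", "G", 0.1),
        FrequencyRecord("chrM", 263, "A", "G", 0.5),
        FrequencyRecord("chrM", 750, "A", "G", 1.0),
    ]


@pytest.fixture
def mito_table(mito_records):
    return build_locus_table(mito_records, build="rCRS")


@pytest.fixture
def labeled_variants():
    return [
        LabeledVariant("chrM", 152, "T", "A", label=0, context="mito_noncoding"),
        LabeledVariant("chrM", 263, "A", "C", label=0, context="mito_noncoding"),
        LabeledVariant("chrM", 5000, "G", "A", label=1, context="mito_noncoding"),
    ]


def random_scores_labels(rng, n, n_distinct=None):
    """A random benchmarking instance with both classes guaranteed."""
    labels = np.zeros(n, int)
    labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[0] = 0
    if n_distinct:
        scores = rng.choice(rng.normal(size=n_distinct), size=n)
    else:
        scores = rng.normal(size=n)
    return scores, labels
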