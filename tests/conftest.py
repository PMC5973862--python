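import numpy as np
import pytest

from lrldkit.genotype_io import MISSING, GenotypeDataset, MarkerInfo, SampleInfo


def make_dataset(calls, markers=None, phenotypes=None, chrom="1", spacing=1000):
    """Build a GenotypeDataset from a (n_samples, n_markers) call matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_markers = calls.shape
    if markers is None:
        markers = [
            MarkerInfo(
                id=f"rs{j + 1}", chrom=chrom, bp=(j + 1) * spacing,
                allele_counted="A", allele_other="G",
            )
            for j in range(n_markers)
        ]
    if phenotypes is None:
        phenotypes = [None] * n_samples
    samples = [
        SampleInfo(id=f"S{i + 1}", phenotype=phenotypes[i]) for i in range(n_samples)
    ]
    return GenotypeDataset(markers=markers, samples=samples, calls=calls)


@pytest.fixture
def small_dataset():
    calls = [
        [0, 1, 2],
        [1, 1, 0],
        [2, MISSING, 1],
        [0, 0, 2],
        [1, 2, MISSING],
    ]
    return make_dataset(calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)
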