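import numpy as np
import pytest

from breedqc.genotype_io import GenotypeMatrix, MarkerMeta, SampleMeta


def make_matrix(dosages, sample_ids=None, marker_meta=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw dosage grid with default metadata."""
    d = np.asarray(dosages, dtype=np.int16)
    n, m = d.shape
    samples = [SampleMeta(id=sample_ids[i] if sample_ids else f"s{i+1:03d}")
               for i in range(n)]
    markers = marker_meta or [
        MarkerMeta(id=f"m{j+1:03d}", alleles=("A", "B"), counted_allele_index=1)
        for j in range(m)
    ]
    return GenotypeMatrix(samples=samples, markers=markers, dosages=d)


@pytest.fixture
def rng():
    return np.random.default_rng(20240821)


@pytest.fixture
def random_panel(rng):
    """An unstructured HWE panel: 30 samples x 80 markers, 5% missing."""
    p = rng.uniform(0.1, 0.9, size=80)
    d = rng.binomial(2, p, size=(30, 80)).astype(np.int16)
    d[rng.uniform(size=d.shape) < 0.05] = -1
    return make_matrix(d)
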