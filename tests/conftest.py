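import numpy as np
import pytest

from domscan.datamodel import GenotypeMatrix, Marker, PedRecord, Pedigree, PhenotypeTable


def make_matrix(rows, sample_prefix="s", chrom="1", cm_spacing=1.0):
    """GenotypeMatrix from a nested list of dosages (None = missing)."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in rows]
    )
    markers = [
        Marker(f"m{j + 1}", chrom, (j + 1) * 1000, "A", "G", cm=j * cm_spacing)
        for j in range(arr.shape[1])
    ]
    samples = [f"{sample_prefix}{i + 1}" for i in range(arr.shape[0])]
    return GenotypeMatrix(samples, markers, arr)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def trio_pedigree():
    """One trio (f, m, child) plus a sire with three half-sib offspring."""
    records = [
        PedRecord("f1", None, None, "male"),
        PedRecord("m1", None, None, "female"),
        PedRecord("c1", "f1", "m1"),
        PedRecord("sireA", None, None, "male"),
        PedRecord("h1", "sireA", None),
        PedRecord("h2", "sireA", None),
        PedRecord("h3", "sireA", None),
    ]
    return Pedigree(records)
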