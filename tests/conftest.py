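import numpy as np
import pytest

from svmerge import (DissimilarityParams, FamilySpec, GenotypeMatrix,
                     PedigreeSpec, SimulationParams, SVRecord, simulate)


def mkrec(id="sv1", chrom="chr1", start=100, end=200, svtype="DEL"):
    return SVRecord(id=id, chrom=chrom, start=start, end=end, svtype=svtype,
                    length=end - start + 1)


@pytest.fixture
def mkrecord():
    return mkrec


def random_instance(rng, n_svs=20, n_samples=6, span=2000):
    """A small random call set on one chromosome with dense positions so
    clusters (and incompatible pairs) actually form."""
    records, rows = [], []
    for i in range(n_svs):
        svtype = rng.choice(["DEL", "DUP"])
        start = int(rng.integers(1, span))
        length = int(rng.integers(60, 400))
        records.append(SVRecord(id=f"r{i:03d}", chrom="chr1", start=start,
                                end=start + length - 1, svtype=svtype,
                                length=length))
        rows.append(rng.choice([0, 0, 0, 1, 2], size=n_samples))
    matrix = GenotypeMatrix(values=np.array(rows, dtype=np.int8),
                            samples=[f"S{j}" for j in range(n_samples)])
    return records, matrix


@pytest.fixture
def small_simulation():
    """500 true SVs, one 3-generation family (2 trios) + 25 unrelated."""
    params = SimulationParams(
        n_true_svs=500,
        pedigree_spec=PedigreeSpec(families=[FamilySpec(1, 1)], n_unrelated=25),
        seed=1)
    return simulate(params)


@pytest.fixture
def d2_params():
    return DissimilarityParams(measure="d2", d_max=200)
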