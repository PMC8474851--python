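"""Randomization null model for cluster genotype composition.

Reshuffling the rows of the genotype matrix within each SV type destroys
the association between genotype vectors and genomic position while
preserving, for any fixed threshold, the cluster size distribution.  Under
this null, decomposed-SV signatures (clusters that collapse into a
Mendelian-consistent variant) arise only by chance, so comparing a
statistic on real data against the ensemble envelope tests whether the
decomposition pattern is a genuine feature of the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .sv_model import GenotypeMatrix, SVRecord

DEFAULT_N_REPLICATES = 10


def randomize(
    matrix: GenotypeMatrix, records: Sequence[SVRecord], seed: int
) -> GenotypeMatrix:
    """Permute genotype rows uniformly at random within each SV type.

    Record coordinates are untouched; only the row-to-position assignment
    changes.  Applied to the pre-correction matrix so that incompatible
    pairs are still removed downstream by the clustering strategy itself.
    """
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    by_type: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_type.setdefault(r.svtype, []).append(i)
    for rows in by_type.values():
        rows = np.array(rows)
        values[rows] = values[rng.permutation(rows)]
    return GenotypeMatrix(values=values, samples=list(matrix.samples))


@dataclass
class RandomEnsemble:
    """An ensemble of row-reshuffled genotype matrices."""

    replicates: list[GenotypeMatrix]
    seed: int

    @classmethod
    def generate(
        cls,
        matrix: GenotypeMatrix,
        records: Sequence[SVRecord],
        seed: int,
        n_replicates: int = DEFAULT_N_REPLICATES,
    ) -> "RandomEnsemble":
        reps = [randomize(matrix, records, seed + k) for k in range(n_replicates)]
        return cls(replicates=reps, seed=seed)


def envelope(
    values_per_replicate: Sequence[Mapping[float, float]],
) -> tuple[dict[float, float], dict[float, float]]:
    """Pointwise min and max across replicate curves (threshold -> statistic)."""
    if not values_per_replicate:
        raise ValueError("empty ensemble")
    keys = list(values_per_replicate[0])
    for curve in values_per_replicate[1:]:
        if list(curve) != keys:
            raise ValueError("replicate curves are on different grids")
    lo = {k: min(c[k] for c in values_per_replicate) for k in keys}
    hi = {k: max(c[k] for c in values_per_replicate) for k in keys}
    return lo, hi
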