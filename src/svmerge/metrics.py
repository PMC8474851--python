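"""Dataset-quality measures for merged SV call sets.

Four families of measures are provided:

* ``trio_f_mei`` — per-trio fraction of informative (non-trivial) SVs whose
  trio genotype configuration is a Mendelian inheritance error;
* ``trio_n_ic`` / ``trio_n_cc`` — per-trio counts of merged clusters whose
  members contained at least one Mendelian error and whose merged
  configuration is consistent (N_ic), and the converse failure mode where
  error-free members merge into an inconsistent configuration (N_cc);
* kinship separation — how cleanly a pairwise relatedness estimator
  (here the proportion of shared alleles, S_xy) separates pedigree kinship
  categories, summarized as a per-category error rate s_i and its mean;
* ``hwe_fraction`` — fraction of polymorphic SVs in Hardy-Weinberg
  equilibrium among unrelated samples after Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .mendelian import RULE, MendelianRule
from .strategies import Clustering
from .sv_model import GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)


@dataclass
class KinshipSeparation:
    """Per-kinship-category separation of a relatedness estimator."""

    categories: list[float]            # relationship coefficients r, increasing
    n_pairs: list[int]                 # pairs per category
    L: list[int]                       # correctly separated pairs per category
    s: list[float]                     # error rate per category
    s_mean: float


def trio_f_mei(
    matrix: GenotypeMatrix, trio: Sequence[str], rule: MendelianRule = RULE
) -> float:
    """Fraction of trio-informative SVs exhibiting a Mendelian error.

    The denominator counts SVs whose trio genotype vector is non-trivial;
    all-reference configurations carry no inheritance information.  Returns
    0 (with a warning) when the trio carries no informative SV at all.
    """
    tv = matrix.trio_vectors(trio)
    nontrivial = tv.any(axis=1)
    n_info = int(nontrivial.sum())
    if n_info == 0:
        logger.warning("trio %s has no informative SVs; f_MEI set to 0", trio)
        return 0.0
    n_mie = sum(1 for u in tv[nontrivial] if not rule.is_consistent(u))
    return n_mie / n_info


def _merged_component_vectors(
    clustering: Clustering, matrix: GenotypeMatrix, trio: Sequence[str]
):
    """Yield (member trio vectors, merged trio vector) for merged components
    of size >= 2."""
    tv = matrix.trio_vectors(trio)
    for comp in clustering.merged_components():
        if len(comp) < 2:
            continue
        members = tv[list(comp)]
        yield members, tuple(int(x) for x in members.sum(axis=0))


def trio_n_ic(
    clustering: Clustering,
    pre_merge_matrix: GenotypeMatrix,
    trio: Sequence[str],
    rule: MendelianRule = RULE,
) -> int:
    """Merged clusters with >= 1 Mendelian-erroneous member whose merged
    configuration is non-trivial and Mendelian-consistent."""
    count = 0
    for members, merged in _merged_component_vectors(clustering, pre_merge_matrix, trio):
        if any(rule.is_mie(u) for u in members) and any(merged) \
                and rule.is_consistent(merged):
            count += 1
    return count


def trio_n_cc(
    clustering: Clustering,
    pre_merge_matrix: GenotypeMatrix,
    trio: Sequence[str],
    rule: MendelianRule = RULE,
) -> int:
    """Merged clusters free of member Mendelian errors whose merged
    configuration nevertheless is a Mendelian error."""
    count = 0
    for members, merged in _merged_component_vectors(clustering, pre_merge_matrix, trio):
        if not any(rule.is_mie(u) for u in members) and rule.is_mie(merged):
            count += 1
    return count


def family_average(per_trio_values: Sequence[float]) -> float:
    """Arithmetic mean over a family's trios."""
    if len(per_trio_values) == 0:
        raise ValueError("family has no trios to average over")
    return float(np.mean(per_trio_values))


def sxy_kinship(matrix: GenotypeMatrix, pair: tuple[str, str]) -> float:
    """Proportion of shared alleles S_xy between two samples.

    At each locus genotypes g, h in {0, 1, 2} share
    ``min(g, h) + min(2 - g, 2 - h)`` of their two alleles.  Loci that are
    monomorphic across the whole cohort are excluded as uninformative;
    loci where only the tested pair is reference are retained.
    """
    a = matrix.values[:, matrix.column(pair[0])].astype(int)
    b = matrix.values[:, matrix.column(pair[1])].astype(int)
    alt = matrix.values.astype(int).sum(axis=1)
    poly = (alt > 0) & (alt < 2 * matrix.n_samples)
    if not poly.any():
        raise ValueError("no polymorphic loci in cohort")
    shared = np.minimum(a, b) + np.minimum(2 - a, 2 - b)
    return float(shared[poly].mean() / 2.0)


def kinship_separation(
    estimates: Mapping[frozenset, float], pedigree: Pedigree
) -> KinshipSeparation:
    """Separation error of a relatedness estimator over kinship categories.

    Categories are the distinct relationship coefficients r present among
    the estimated pairs, in increasing order.  A pair in category i is
    *separated* when its estimate lies strictly above the maximum estimate
    of category i-1 and strictly below the minimum of category i+1 (missing
    neighbors count as -inf / +inf).  s_i = 1 - L_i / n_pairs_i; the
    summary is the unweighted mean of s_i.  Categories with fewer than two
    pairs are skipped with a warning.
    """
    by_r: dict[float, list[float]] = {}
    for pair, est in estimates.items():
        r = pedigree.kinship_pairs.get(frozenset(pair))
        if r is None:
            raise ValueError(f"pair {set(pair)} has no pedigree relationship coefficient")
        by_r.setdefault(round(r, 6), []).append(est)
    cats = sorted(by_r)
    kept = [r for r in cats if len(by_r[r]) >= 2]
    for r in cats:
        if r not in kept:
            logger.warning("kinship category r=%s has < 2 pairs; skipped", r)
    L_list, s_list, n_list = [], [], []
    for idx, r in enumerate(kept):
        lo = max(by_r[kept[idx - 1]]) if idx > 0 else -np.inf
        hi = min(by_r[kept[idx + 1]]) if idx + 1 < len(kept) else np.inf
        vals = by_r[r]
        L = sum(1 for v in vals if lo < v < hi)
        L_list.append(L)
        n_list.append(len(vals))
        s_list.append(1.0 - L / len(vals))
    if not s_list:
        raise ValueError("no kinship category has >= 2 pairs")
    return KinshipSeparation(categories=kept, n_pairs=n_list, L=L_list, s=s_list,
                             s_mean=float(np.mean(s_list)))


def hwe_fraction(
    matrix: GenotypeMatrix, unrelated: Sequence[str], alpha: float = 0.05
) -> tuple[float, np.ndarray]:
    """Fraction of polymorphic SVs in Hardy-Weinberg equilibrium.

    Per polymorphic SV (minor allele present among the unrelated samples), a
    1-df Pearson chi-square compares observed genotype counts with the
    p^2 / 2pq / q^2 expectation; p-values are Bonferroni-corrected by the
    number of tested SVs.  Returns (f_HWeq, raw p-values of tested SVs).
    """
    if len(unrelated) == 0:
        raise ValueError("empty unrelated sample set")
    cols = [matrix.column(s) for s in unrelated]
    sub = matrix.values[:, cols].astype(int)
    n = sub.shape[1]
    pvals = []
    for row in sub:
        n0 = int((row == 0).sum())
        n1 = int((row == 1).sum())
        n2 = int((row == 2).sum())
        alt = n1 + 2 * n2
        if alt == 0 or alt == 2 * n:
            continue  # monomorphic: untestable
        q = alt / (2 * n)
        p = 1 - q
        expected = np.array([p * p, 2 * p * q, q * q]) * n
        chi2 = float((((np.array([n0, n1, n2]) - expected) ** 2) / expected).sum())
        pvals.append(stats.chi2.sf(chi2, df=1))
    if not pvals:
        return 1.0, np.array([])
    pvals = np.array(pvals)
    m = len(pvals)
    corrected = np.minimum(pvals * m, 1.0)
    return float((corrected >= alpha).mean()), pvals
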