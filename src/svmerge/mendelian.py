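"""Mendelian consistency of trio genotype configurations.

A trio configuration is a vector u = (child, parent1, parent2) with entries
in {0, 1, 2} counting alternate alleles.  It is Mendelian-consistent when
the child's two alleles can be drawn one from each parent: a parent with
genotype 0 transmits a reference allele, genotype 2 transmits an alternate
allele, genotype 1 may transmit either.  u is *non-trivial* if any entry is
non-zero; trivial (0,0,0) configurations carry no inheritance information
but are vacuously consistent.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Iterable

import numpy as np

TrioVector = tuple[int, int, int]

_TRANSMIT = {0: (0,), 1: (0, 1), 2: (1,)}


def _consistent(c: int, p1: int, p2: int) -> bool:
    return any(t1 + t2 == c for t1 in _TRANSMIT[p1] for t2 in _TRANSMIT[p2])


class MendelianRule:
    """The set of trio genotype vectors consistent with Mendelian inheritance.

    Built once by enumerating all 27 configurations; closed under swapping
    the two parents.
    """

    def __init__(self) -> None:
        self.consistent_set: frozenset[TrioVector] = frozenset(
            u for u in product((0, 1, 2), repeat=3) if _consistent(*u)
        )

    def is_consistent(self, u: Iterable[int]) -> bool:
        u = tuple(int(x) for x in u)
        if len(u) != 3 or any(x not in (0, 1, 2) for x in u):
            raise ValueError(f"not a trio genotype vector: {u}")
        return u in self.consistent_set

    def is_mie(self, u: Iterable[int]) -> bool:
        """Mendelian inheritance error: non-trivial and inconsistent."""
        u = tuple(int(x) for x in u)
        return any(u) and not self.is_consistent(u)


RULE = MendelianRule()


def is_mendelian_consistent(u: Iterable[int], rule: MendelianRule = RULE) -> bool:
    return rule.is_consistent(u)


def is_nontrivial(u: Iterable[int]) -> bool:
    return any(int(x) != 0 for x in u)


def _disjoint_support(vectors: Iterable[TrioVector]) -> bool:
    support = np.array([[x != 0 for x in v] for v in vectors])
    return not np.any(support.sum(axis=0) > 1)


def enumerate_mergeable_patterns(
    rule: MendelianRule = RULE,
) -> tuple[set[frozenset[TrioVector]], set[frozenset[TrioVector]]]:
    """All unordered pairs and triplets of non-trivial trio vectors with
    pairwise disjoint support whose elementwise sum is Mendelian-consistent.

    These are exactly the trio-level signatures a decomposed SV can leave:
    one true variant reported as 2-3 records whose carrier sets partition
    the true carriers.  Adding a fourth non-trivial disjoint-support vector
    is impossible (only three positions exist), which bounds the
    combinatorial search.
    """
    nontrivial = [u for u in product((0, 1, 2), repeat=3) if any(u)]
    pairs: set[frozenset[TrioVector]] = set()
    triplets: set[frozenset[TrioVector]] = set()
    for u, v in combinations(nontrivial, 2):
        if _disjoint_support((u, v)) and rule.is_consistent(
                tuple(a + b for a, b in zip(u, v))):
            pairs.add(frozenset((u, v)))
    for u, v, w in combinations(nontrivial, 3):
        if _disjoint_support((u, v, w)) and rule.is_consistent(
                tuple(a + b + c for a, b, c in zip(u, v, w))):
            triplets.add(frozenset((u, v, w)))
    return pairs, triplets
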