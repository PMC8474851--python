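"""Trio-constrained clustering of structural variants.

The method exploits parent-child trios to recognize *decomposed* SVs: one
true variant reported as two or three nearby records whose carrier sets
partition the true carriers.  At the trio level such a decomposition leaves
a characteristic signature — a set of non-trivial genotype vectors with
disjoint support whose sum is Mendelian-consistent (26 possible pairs,
7 possible triplets).

The pipeline is:

1. combinatorial search for candidate SV groups matching a mergeable
   signature in some trio, compatible across *all* samples and within the
   dissimilarity threshold;
2. reduction of overlapping groups to a disjoint accepted set (greedy, by
   number of supporting trios, random tie-break);
3. agglomerative clustering seeded with the accepted groups as must-link
   components, joining nearest pairs in ascending dissimilarity order while
   rejecting any union that would put a merging-incompatible (cannot-link)
   pair in one component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .dissimilarity import DissimilarityParams, threshold_graph
from .mendelian import RULE, MendelianRule, enumerate_mergeable_patterns
from .strategies import Clustering, _component_sort_key
from .sv_model import GenotypeMatrix, Pedigree, SVRecord


@dataclass
class SVGroup:
    """A candidate set of 2-3 SV rows mergeable into one Mendelian-consistent
    variant, with the trios in which its signature was detected."""

    members: frozenset[int]
    trios_detected_in: set[int] = field(default_factory=set)
    component_id: int = -1   # assigned during reduction


def find_sv_groups(
    matrix: GenotypeMatrix,
    records: list[SVRecord],
    pedigree: Pedigree,
    params: DissimilarityParams,
    patterns: tuple[set, set] | None = None,
    graph: nx.Graph | None = None,
) -> list[SVGroup]:
    """Search every trio for SV pairs and triplets that merge into a
    Mendelian-consistent variant.

    A group must (1) be merging-compatible over all samples, not just the
    trio, and (2) have every member pair within d_max.  Identical member
    sets found in several trios are returned as one group with all
    supporting trios recorded.
    """
    if patterns is None:
        patterns = enumerate_mergeable_patterns()
    pair_patterns, triplet_patterns = patterns
    if graph is None:
        graph = threshold_graph(records, params)
    nz = matrix.values != 0
    found: dict[frozenset, SVGroup] = {}

    def emit(members: tuple[int, ...], trio_idx: int) -> None:
        key = frozenset(members)
        grp = found.get(key)
        if grp is None:
            grp = found[key] = SVGroup(members=key)
        grp.trios_detected_in.add(trio_idx)

    adj = {n: {m for m in graph[n] if m > n} for n in graph}
    for t_idx, trio in enumerate(pedigree.trios):
        tv = matrix.trio_vectors(trio)
        nontrivial = tv.any(axis=1)
        for i, j in graph.edges():
            if not (nontrivial[i] and nontrivial[j]):
                continue
            sig = frozenset((tuple(tv[i]), tuple(tv[j])))
            if sig not in pair_patterns:
                continue
            if np.any(nz[i] & nz[j]):
                continue  # condition 1: incompatible over all samples
            emit((i, j), t_idx)
        # triplets: triangles in the threshold graph
        for i in sorted(graph):
            if not nontrivial[i]:
                continue
            for j in sorted(adj[i]):
                if not nontrivial[j]:
                    continue
                for k in sorted(adj[i] & adj[j]):
                    if not nontrivial[k]:
                        continue
                    sig = frozenset((tuple(tv[i]), tuple(tv[j]), tuple(tv[k])))
                    if sig not in triplet_patterns:
                        continue
                    support = nz[[i, j, k]]
                    if np.any(support.sum(axis=0) > 1):
                        continue
                    emit((i, j, k), t_idx)
    return sorted(found.values(), key=lambda g: sorted(g.members))


def reduce_to_disjoint(
    groups: list[SVGroup],
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    seed: int,
    rule: MendelianRule = RULE,
) -> list[SVGroup]:
    """Greedy reduction of overlapping candidate groups to an accepted set.

    Groups sharing an SV form the vertices of an intersection graph; within
    each connected component, groups are taken by descending number of
    supporting trios (seeded random tie-break).  A group is accepted if its
    rows are merging-compatible with everything already accepted in the
    component and the merged genotype vector is Mendelian-consistent (or
    trivial) in every trio.  Accepted groups keep a shared ``component_id``
    marking the reduced component they belong to.
    """
    rng = np.random.default_rng(seed)
    inter = nx.Graph()
    inter.add_nodes_from(range(len(groups)))
    for a, b in combinations(range(len(groups)), 2):
        if groups[a].members & groups[b].members:
            inter.add_edge(a, b)
    nz = matrix.values != 0
    trio_cols = [[matrix.column(s) for s in trio] for trio in pedigree.trios]
    accepted: list[SVGroup] = []
    comps = sorted(nx.connected_components(inter),
                   key=lambda c: min(sorted(groups[g].members) for g in c))
    for comp_id, comp in enumerate(comps):
        queue = sorted(comp, key=lambda g: sorted(groups[g].members))
        acc_rows: set[int] = set()
        while queue:
            best = max(len(groups[g].trios_detected_in) for g in queue)
            top = [g for g in queue if len(groups[g].trios_detected_in) == best]
            pick = top[0] if len(top) == 1 else top[rng.integers(len(top))]
            queue.remove(pick)
            grp = groups[pick]
            cand = acc_rows | grp.members
            rows = sorted(cand)
            if np.any(nz[rows].sum(axis=0) > 1):
                continue  # merging-incompatible with accepted set
            merged = matrix.values[rows].sum(axis=0)
            ok = True
            for cols in trio_cols:
                u = tuple(int(merged[c]) for c in cols)
                if any(u) and not rule.is_consistent(u):
                    ok = False
                    break
            if ok:
                acc_rows = cand
                accepted.append(SVGroup(members=grp.members,
                                        trios_detected_in=set(grp.trios_detected_in),
                                        component_id=comp_id))
    return accepted


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)
        return min(ra, rb)


def constrained_clustering(
    matrix: GenotypeMatrix,
    records: list[SVRecord],
    pedigree: Pedigree,
    params: DissimilarityParams,
    seed: int = 0,
    rule: MendelianRule = RULE,
) -> Clustering:
    """Cannot-link constrained agglomerative clustering seeded with trio groups.

    Accepted groups from the reduction step pre-link their members (a whole
    reduced component forms one initial must-link cluster).  Remaining
    candidate pairs within d_max are then processed in ascending
    dissimilarity order; a link joining two clusters is accepted only if no
    sample would end up non-reference in two member rows.  The procedure
    stops when no cross-cluster pair at dissimilarity <= d_max remains.
    """
    n = matrix.n_svs
    graph = threshold_graph(records, params)
    patterns = enumerate_mergeable_patterns(rule)
    groups = find_sv_groups(matrix, records, pedigree, params,
                            patterns=patterns, graph=graph)
    accepted = reduce_to_disjoint(groups, matrix, pedigree, seed, rule)

    uf = _UnionFind(n)
    carriers = {i: matrix.values[i] != 0 for i in range(n)}

    def link(a: int, b: int) -> None:
        ra, rb = uf.find(a), uf.find(b)
        if ra == rb:
            return
        ca, cb = carriers.pop(ra), carriers.pop(rb)
        carriers[uf.union(ra, rb)] = ca | cb

    # must-link: every reduced component is one initial cluster
    by_component: dict[int, list[int]] = {}
    for grp in accepted:
        by_component.setdefault(grp.component_id, []).extend(grp.members)
    for members in by_component.values():
        for other in members[1:]:
            link(members[0], other)

    def tie_key(i: int, j: int):
        ri, rj = records[i], records[j]
        a, b = sorted(((ri.chrom, ri.start, ri.id), (rj.chrom, rj.start, rj.id)))
        return (*a, *b)

    edges = sorted(((d, i, j) for i, j, d in graph.edges(data="d")),
                   key=lambda e: (e[0], tie_key(e[1], e[2])))
    for d, i, j in edges:
        ra, rb = uf.find(i), uf.find(j)
        if ra == rb:
            continue
        if not np.any(carriers[ra] & carriers[rb]):
            link(i, j)

    by_root: dict[int, list[int]] = {}
    for i in range(n):
        by_root.setdefault(uf.find(i), []).append(i)
    comps = sorted((tuple(sorted(m)) for m in by_root.values()),
                   key=_component_sort_key(records))
    return Clustering(components=comps, merged=[True] * len(comps),
                      strategy="constrained", params=params,
                      meta={"n_candidate_groups": len(groups),
                            "n_accepted_groups": len(accepted),
                            "seed": seed})
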