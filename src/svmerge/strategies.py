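"""Trivial and corrected clustering strategies, and merged-call-set output.

Both strategies start from the connected components of the threshold graph.
The *trivial* strategy refuses to merge any component containing a
merging-incompatible pair, keeping all its members as separate records.
The *corrected* strategy instead searches for the maximal threshold
D < d_max at which the component decomposes into sub-components that are
all incompatibility-free, and merges those sub-components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from typing import Sequence

import networkx as nx
import numpy as np

from .dissimilarity import DissimilarityParams, threshold_graph
from .sv_model import (GenotypeMatrix, SVRecord, merge_genotypes,
                       rows_pairwise_compatible)


@dataclass
class Clustering:
    """A partition of SV row indices into components.

    ``merged`` flags whether each component is collapsed into a single
    record on output; unmerged components (trivial strategy only) keep every
    member as its own record.
    """

    components: list[tuple[int, ...]]
    merged: list[bool]
    strategy: str = ""
    params: DissimilarityParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for comp in self.components:
            if seen & set(comp):
                raise ValueError("components are not a partition")
            seen |= set(comp)

    @property
    def n_input_rows(self) -> int:
        return sum(len(c) for c in self.components)

    def merged_components(self) -> list[tuple[int, ...]]:
        return [c for c, m in zip(self.components, self.merged) if m]


def _component_sort_key(records: Sequence[SVRecord]):
    def key(comp: tuple[int, ...]):
        r = records[min(comp, key=lambda i: (records[i].chrom, records[i].start, records[i].id))]
        return (r.chrom, r.start, r.id)
    return key


def trivial_strategy(
    matrix: GenotypeMatrix, records: list[SVRecord], params: DissimilarityParams
) -> Clustering:
    """Merge a component only if it is free of merging-incompatible pairs."""
    graph = threshold_graph(records, params)
    pairs = []
    for comp in nx.connected_components(graph):
        comp = tuple(sorted(comp))
        pairs.append((comp, rows_pairwise_compatible(comp, matrix)))
    key = _component_sort_key(records)
    pairs.sort(key=lambda cm: key(cm[0]))
    return Clustering(components=[c for c, _ in pairs], merged=[m for _, m in pairs],
                      strategy="trivial", params=params)


def _split_component(
    comp: tuple[int, ...],
    graph: nx.Graph,
    matrix: GenotypeMatrix,
    d_max: float,
) -> list[tuple[int, ...]]:
    """Maximal-threshold split of one conflicted component.

    Candidate thresholds are the realized pairwise dissimilarities within the
    component that are strictly below d_max, scanned in descending order;
    sub-component structure only changes at those values.  The first
    threshold whose induced sub-components are all incompatibility-free
    wins.  If even the smallest realized dissimilarity links an incompatible
    pair (e.g. two incompatible SVs at identical coordinates), the component
    falls back to singletons.
    """
    sub = graph.subgraph(comp)
    dvals = sorted({d for _, _, d in sub.edges(data="d") if d < d_max}, reverse=True)
    for thr in dvals:
        g = nx.Graph()
        g.add_nodes_from(comp)
        g.add_edges_from((u, v) for u, v, d in sub.edges(data="d") if d <= thr)
        pieces = [tuple(sorted(c)) for c in nx.connected_components(g)]
        if all(rows_pairwise_compatible(p, matrix) for p in pieces):
            return pieces
    return [(i,) for i in comp]


def corrected_strategy(
    matrix: GenotypeMatrix, records: list[SVRecord], params: DissimilarityParams
) -> Clustering:
    """Split conflicted components at the maximal incompatibility-free
    threshold below d_max; merge every resulting component."""
    graph = threshold_graph(records, params)
    comps: list[tuple[int, ...]] = []
    for comp in nx.connected_components(graph):
        comp = tuple(sorted(comp))
        if rows_pairwise_compatible(comp, matrix):
            comps.append(comp)
        else:
            comps.extend(_split_component(comp, graph, matrix, params.d_max))
    comps.sort(key=_component_sort_key(records))
    return Clustering(components=comps, merged=[True] * len(comps),
                      strategy="corrected", params=params)


def materialize(
    clustering: Clustering, records: list[SVRecord], matrix: GenotypeMatrix
) -> tuple[list[SVRecord], GenotypeMatrix, list[dict]]:
    """Build the output call set for a clustering.

    A merged component becomes one record spanning min start / max end of
    its members, with the lexicographically smallest member ID; its genotype
    row is the member sum.  Unmerged components contribute their members
    unchanged.  The third return value lists per-record INFO metadata
    (MEMBERS, MERGED, STRATEGY) for VCF output.
    """
    out_records: list[SVRecord] = []
    out_rows: list[np.ndarray] = []
    info: list[dict] = []
    for comp, merged in zip(clustering.components, clustering.merged):
        if merged:
            members = sorted(comp, key=lambda i: records[i].id)
            rep = records[members[0]]
            start = min(records[i].start for i in comp)
            end = max(records[i].end for i in comp)
            out_records.append(SVRecord(
                id=rep.id, chrom=rep.chrom, start=start, end=end,
                svtype=rep.svtype, length=end - start + 1,
                pseudo_interval=any(records[i].pseudo_interval for i in comp)))
            out_rows.append(merge_genotypes(comp, matrix))
            info.append({"MEMBERS": ",".join(records[i].id for i in members),
                         "MERGED": 1, "STRATEGY": clustering.strategy or "none"})
        else:
            for i in sorted(comp, key=lambda i: (records[i].start, records[i].id)):
                out_records.append(records[i])
                out_rows.append(matrix.values[i].copy())
                info.append({"MEMBERS": records[i].id, "MERGED": 0,
                             "STRATEGY": clustering.strategy or "none"})
    values = (np.vstack(out_rows) if out_rows
              else np.empty((0, matrix.n_samples), np.int8))
    return out_records, GenotypeMatrix(values=values, samples=list(matrix.samples)), info
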