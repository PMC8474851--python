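"""Dissimilarity measures between SV records and the threshold graph.

Two measures are supported.  ``d1`` is overlap-based:

    D1 = 1 - |g1 & g2| / max(|g1|, |g2|)

so identical intervals score 0 and disjoint intervals score 1.  ``d2`` is
breakpoint-distance based:

    D2 = max(|start1 - start2|, |end1 - end2|)

in base pairs.  Clusters are the connected components of the graph whose
edges join same-chromosome, same-type SV pairs with dissimilarity at most
``d_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .sv_model import SVRecord

D1_GRID_DEFAULT = [round(0.05 * k, 2) for k in range(1, 20)]   # 0.05 .. 0.95
D2_GRID_DEFAULT = [50 * k for k in range(1, 21)]               # 50 .. 1000 bp


@dataclass
class DissimilarityParams:
    """Measure choice and clustering threshold.

    For D1 the threshold is unitless in [0, 1); the maximum value 1 means
    "disjoint" and is never a useful threshold.  For D2 the threshold is a
    breakpoint distance in bp (>= 0).
    """

    measure: str = "d2"
    d_max: float = 150.0
    grid: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.measure = self.measure.lower()
        if self.measure not in ("d1", "d2"):
            raise ValueError(f"unknown dissimilarity measure {self.measure!r}")
        if self.measure == "d1" and not (0 <= self.d_max < 1):
            raise ValueError("D1 threshold must lie in [0, 1)")
        if self.measure == "d2" and self.d_max < 0:
            raise ValueError("D2 threshold must be non-negative")
        if not self.grid:
            self.grid = list(D1_GRID_DEFAULT if self.measure == "d1" else D2_GRID_DEFAULT)

    def dissimilarity(self, a: SVRecord, b: SVRecord) -> float:
        return d1(a, b) if self.measure == "d1" else d2(a, b)


def _check_comparable(a: SVRecord, b: SVRecord) -> None:
    if a.chrom != b.chrom:
        raise ValueError(f"records {a.id}, {b.id} on different chromosomes")
    if a.svtype != b.svtype:
        raise ValueError(f"records {a.id}, {b.id} of different SV types")


def d1(a: SVRecord, b: SVRecord) -> float:
    """Overlap dissimilarity in [0, 1]; 0 iff identical intervals, 1 iff disjoint."""
    _check_comparable(a, b)
    denom = max(a.end - a.start + 1, b.end - b.start + 1)
    return 1.0 - a.overlap(b) / denom


def d2(a: SVRecord, b: SVRecord) -> float:
    """Maximum breakpoint distance in bp; a metric on intervals."""
    _check_comparable(a, b)
    return float(max(abs(a.start - b.start), abs(a.end - b.end)))


def candidate_edges(
    records: list[SVRecord], params: DissimilarityParams
) -> list[tuple[int, int, float]]:
    """All (i, j, dissimilarity) triples with dissimilarity <= d_max.

    Uses a sorted sweep over (chrom, svtype, start) so only nearby pairs are
    evaluated: for D2 a candidate's start must lie within d_max of the
    anchor's start; for D1 (< 1) the intervals must overlap, so the
    candidate's start must not exceed the anchor's end.
    """
    order = sorted(range(len(records)),
                   key=lambda i: (records[i].chrom, records[i].svtype,
                                  records[i].start, records[i].id))
    edges: list[tuple[int, int, float]] = []
    for a_pos, i in enumerate(order):
        ri = records[i]
        for j in order[a_pos + 1:]:
            rj = records[j]
            if (rj.chrom, rj.svtype) != (ri.chrom, ri.svtype):
                break
            if params.measure == "d2":
                if rj.start - ri.start > params.d_max:
                    break
            else:
                if rj.start > ri.end:  # no overlap possible => D1 = 1
                    break
            d = params.dissimilarity(ri, rj)
            if d <= params.d_max:
                edges.append((min(i, j), max(i, j), d))
    return edges


def threshold_graph(records: list[SVRecord], params: DissimilarityParams) -> nx.Graph:
    """Graph on SV indices with edges where dissimilarity <= d_max.

    Every record index is a node, so isolated SVs appear as singleton
    components.  Edge attribute ``d`` carries the dissimilarity value.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(records)))
    for i, j, d in candidate_edges(records, params):
        g.add_edge(i, j, d=d)
    return g
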