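"""Independent brute-force reference implementations used as test oracles.

Deliberately written in the most direct way possible (all-pairs double
loops, breadth-first components, explicit allele multisets) so they share
no code path with the package implementation.
"""

from itertools import combinations


def brute_dissimilarity(a, b, measure):
    if measure == "d1":
        ov = max(0, min(a.end, b.end) - max(a.start, b.start) + 1)
        return 1 - ov / max(a.end - a.start + 1, b.end - b.start + 1)
    return max(abs(a.start - b.start), abs(a.end - b.end))


def brute_graph_components(records, measure, d_max):
    """Components of the all-pairs threshold graph, by BFS."""
    n = len(records)
    adj = {i: set() for i in range(n)}
    for i, j in combinations(range(n), 2):
        a, b = records[i], records[j]
        if a.chrom != b.chrom or a.svtype != b.svtype:
            continue
        if brute_dissimilarity(a, b, measure) <= d_max:
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        queue, comp = [i], set()
        while queue:
            x = queue.pop()
            if x in comp:
                continue
            comp.add(x)
            queue.extend(adj[x] - comp)
        seen |= comp
        comps.append(tuple(sorted(comp)))
    return sorted(comps)


def has_incompatible_pair(rows, matrix):
    for i, j in combinations(sorted(rows), 2):
        vi, vj = matrix.values[i], matrix.values[j]
        if any(int(a) != 0 and int(b) != 0 for a, b in zip(vi, vj)):
            return True
    return False


def brute_trivial(records, matrix, measure, d_max):
    """(component, merged?) pairs of the trivial strategy."""
    return [(comp, not has_incompatible_pair(comp, matrix))
            for comp in brute_graph_components(records, measure, d_max)]


def brute_corrected(records, matrix, measure, d_max):
    """Corrected-strategy partition by exhaustive threshold scan."""
    out = []
    for comp in brute_graph_components(records, measure, d_max):
        if not has_incompatible_pair(comp, matrix):
            out.append(comp)
            continue
        dvals = sorted({brute_dissimilarity(records[i], records[j], measure)
                        for i, j in combinations(comp, 2)
                        if records[i].chrom == records[j].chrom
                        and records[i].svtype == records[j].svtype}
                       | {0.0})
        best = None
        for thr in dvals:
            if thr >= d_max:
                continue
            pieces = _components_at(comp, records, measure, thr)
            if all(not has_incompatible_pair(p, matrix) for p in pieces):
                best = pieces  # keep scanning: take the largest valid thr
        if best is None:
            best = [(i,) for i in comp]
        out.extend(best)
    return sorted(out)


def _components_at(nodes, records, measure, thr):
    adj = {i: set() for i in nodes}
    for i, j in combinations(nodes, 2):
        a, b = records[i], records[j]
        if a.chrom == b.chrom and a.svtype == b.svtype \
                and brute_dissimilarity(a, b, measure) <= thr:
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in nodes:
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(tuple(sorted(comp)))
    return comps


def allele_multiset_consistent(child, p1, p2):
    """Mendelian consistency via explicit transmitted-allele multisets."""
    def transmissible(g):
        alleles = [1] * g + [0] * (2 - g)
        return set(alleles)
    return any(a + b == child
               for a in transmissible(p1) for b in transmissible(p2))
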