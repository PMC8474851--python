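"""Synthetic pedigreed SV call sets with controlled breakpoint errors.

The generator emulates the situation the clustering strategies are built
for: true SV loci segregate through three-generation families (genotypes by
gene-dropping, so the true matrix is Mendelian-error-free) plus a panel of
unrelated individuals in Hardy-Weinberg proportions.  Two error processes
corrupt the reported call set:

* *breakpoint jitter* — with probability ``p_jitter`` a record's reported
  start/end are shifted by geometric offsets, emulating imprecise
  breakpoint resolution;
* *decomposition* — with probability ``p_decompose`` a true SV's carriers
  are split into 2-3 non-empty subsets, each reported as a separate record
  at a shifted position.  The emitted records have disjoint carrier sets
  that sum back to the true genotype row, which is exactly the pattern the
  trio-constrained clustering method searches for.

In addition, a fraction ``p_hotspot`` of true SVs are *recurrent*: placed
with near-identical breakpoints next to a previously drawn SV of the same
type, emulating repeat-mediated hotspot variants.  Distinct recurrent SVs
frequently share carriers, so they populate clusters with genuinely
merging-incompatible pairs — the situation that separates the clustering
strategies from one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sv_model import GenotypeMatrix, Pedigree, SVRecord
from .strategies import Clustering

SVTYPE_WEIGHTS_DEFAULT = {"DEL": 0.5, "DUP": 0.2, "INV": 0.15, "INS": 0.15}


@dataclass
class FamilySpec:
    """One three-generation family: a grandparental couple, their children
    (each married to an unrelated founder spouse), and grandchildren."""

    n_gen2_children: int = 2
    n_gen3_per_couple: int = 2


@dataclass
class PedigreeSpec:
    families: list[FamilySpec] = field(
        default_factory=lambda: [FamilySpec(2, 2), FamilySpec(2, 3)])
    n_unrelated: int = 102


@dataclass
class SimulationParams:
    """Study conditions for the generator.

    Lengths are log-uniform on [51 bp, 100 kb]; allele frequencies are
    Beta-distributed (defaults skewed toward rare variants, as SV frequency
    spectra are); jitter offsets are geometric with the given mean.  The
    default pedigree mirrors a cohort with two three-generation families
    (10 and 12 members) plus 102 unrelated individuals.
    """

    n_true_svs: int = 1000
    sv_type_weights: dict[str, float] = field(
        default_factory=lambda: dict(SVTYPE_WEIGHTS_DEFAULT))
    length_range: tuple[int, int] = (51, 100_000)
    af_beta: tuple[float, float] = (0.5, 3.0)
    pedigree_spec: PedigreeSpec = field(default_factory=PedigreeSpec)
    p_jitter: float = 0.2
    jitter_mean: float = 30.0
    p_decompose: float = 0.2
    p_hotspot: float = 0.15
    hotspot_offset_mean: float = 50.0
    n_chromosomes: int = 2
    chromosome_length: int = 10_000_000
    seed: int = 0


@dataclass
class GroundTruth:
    """Mapping between true SV loci and the emitted (possibly decomposed,
    possibly jittered) records."""

    true_records: list[SVRecord]
    true_matrix: GenotypeMatrix
    emitted_of: dict[str, list[str]]       # true id -> emitted record ids
    true_of: dict[str, str]                # emitted record id -> true id

    @property
    def decomposed_ids(self) -> list[str]:
        return [t for t, e in self.emitted_of.items() if len(e) >= 2]


def build_pedigree(spec: PedigreeSpec) -> tuple[Pedigree, list[tuple]]:
    """Construct the Pedigree object and its PED-file rows."""
    rows: list[tuple] = []   # (fam, ind, pat, mat, sex, pheno)
    for f_idx, fam in enumerate(spec.families):
        famid = f"FAM{f_idx + 1}"
        gp1, gp2 = f"{famid}_GP1", f"{famid}_GP2"
        rows.append((famid, gp1, "0", "0", 1, 0))
        rows.append((famid, gp2, "0", "0", 2, 0))
        for c in range(1, fam.n_gen2_children + 1):
            child = f"{famid}_C{c}"
            spouse = f"{famid}_S{c}"
            child_sex = 1 if c % 2 == 1 else 2
            rows.append((famid, child, gp1, gp2, child_sex, 0))
            rows.append((famid, spouse, "0", "0", 3 - child_sex, 0))
            father, mother = (child, spouse) if child_sex == 1 else (spouse, child)
            for g in range(1, fam.n_gen3_per_couple + 1):
                gc = f"{famid}_C{c}G{g}"
                rows.append((famid, gc, father, mother, 1 if g % 2 else 2, 0))
    for u in range(1, spec.n_unrelated + 1):
        rows.append((f"U{u}", f"U{u}", "0", "0", 1 if u % 2 else 2, 0))
    if not rows:
        raise ValueError("pedigree specification produces no individuals")

    from .sv_model import read_pedigree
    import os
    import tempfile
    with tempfile.NamedTemporaryFile("w", suffix=".ped", delete=False) as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
        path = fh.name
    try:
        ped = read_pedigree(path)
    finally:
        os.unlink(path)
    return ped, rows


def write_ped(path: str, rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def _gene_drop(rows: list[tuple], q: float, rng: np.random.Generator) -> dict[str, int]:
    """Drop one biallelic locus with alt frequency q through the pedigree."""
    alleles: dict[str, tuple[int, int]] = {}
    for fam, ind, pat, mat, _sex, _ph in rows:
        if pat == "0":
            alleles[ind] = (int(rng.random() < q), int(rng.random() < q))
        else:
            pa, ma = alleles[pat], alleles[mat]
            alleles[ind] = (pa[rng.integers(2)], ma[rng.integers(2)])
    return {ind: a + b for ind, (a, b) in alleles.items()}


def _geometric_offset(rng: np.random.Generator, mean: float) -> int:
    """Non-zero symmetric geometric offset with the given mean magnitude."""
    mag = 1 + rng.geometric(1.0 / max(mean, 1.0))
    return int(mag) * (1 if rng.random() < 0.5 else -1)


def _shift_interval(
    start: int, end: int, rng: np.random.Generator, mean: float, min_len: int = 51
) -> tuple[int, int]:
    """Independently offset both breakpoints, keeping length >= min_len."""
    s = max(1, start + _geometric_offset(rng, mean))
    e = end + _geometric_offset(rng, mean)
    if e - s + 1 < min_len:
        e = s + min_len - 1
    return s, e


def simulate(
    params: SimulationParams,
) -> tuple[list[SVRecord], GenotypeMatrix, Pedigree, GroundTruth]:
    """Generate an observed call set with known ground truth.

    Returns records sorted by (chrom, start, id), the observed genotype
    matrix aligned to them, the pedigree, and the ground-truth bookkeeping.
    """
    rng = np.random.default_rng(params.seed)
    pedigree, ped_rows = build_pedigree(params.pedigree_spec)
    samples = pedigree.samples
    n_samples = len(samples)
    col = {s: j for j, s in enumerate(samples)}

    types = sorted(params.sv_type_weights)
    weights = np.array([params.sv_type_weights[t] for t in types], dtype=float)
    weights /= weights.sum()
    lo, hi = params.length_range
    chroms = [f"chr{c + 1}" for c in range(params.n_chromosomes)]

    true_records: list[SVRecord] = []
    true_rows: list[np.ndarray] = []
    emitted: list[SVRecord] = []
    emitted_rows: list[np.ndarray] = []
    emitted_of: dict[str, list[str]] = {}
    true_of: dict[str, str] = {}

    for t in range(params.n_true_svs):
        tid = f"t{t + 1:05d}"
        if true_records and rng.random() < params.p_hotspot:
            # recurrent SV: near-identical breakpoints to an earlier one
            base = true_records[rng.integers(len(true_records))]
            svtype, chrom = base.svtype, base.chrom
            start = max(1, base.start + _geometric_offset(rng, params.hotspot_offset_mean))
            end = base.end + _geometric_offset(rng, params.hotspot_offset_mean)
            if end - start + 1 < lo:
                end = start + lo - 1
            length = end - start + 1
        else:
            svtype = types[rng.choice(len(types), p=weights)]
            length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(1, params.chromosome_length - length))
            end = start + length - 1
        q = float(rng.beta(*params.af_beta))
        genos = _gene_drop(ped_rows, q, rng)
        row = np.array([genos[s] for s in samples], dtype=np.int8)
        true_records.append(SVRecord(id=tid, chrom=chrom, start=start, end=end,
                                     svtype=svtype, length=length,
                                     pseudo_interval=svtype == "INS"))
        true_rows.append(row)
        emitted_of[tid] = []

        carriers = [s for s in samples if row[col[s]] > 0]
        n_parts = 1
        if len(carriers) >= 2 and rng.random() < params.p_decompose:
            n_parts = 2 if (len(carriers) < 3 or rng.random() < 2 / 3) else 3
        if n_parts == 1:
            s0, e0 = start, end
            if rng.random() < params.p_jitter:
                s0, e0 = _shift_interval(start, end, rng, params.jitter_mean)
            eid = f"{tid}.0"
            emitted.append(SVRecord(id=eid, chrom=chrom, start=s0, end=e0,
                                    svtype=svtype, length=e0 - s0 + 1,
                                    pseudo_interval=svtype == "INS"))
            emitted_rows.append(row.copy())
            emitted_of[tid].append(eid)
            true_of[eid] = tid
        else:
            order = list(rng.permutation(len(carriers)))
            cuts = sorted(rng.choice(np.arange(1, len(carriers)), size=n_parts - 1,
                                     replace=False))
            parts, prev = [], 0
            for c in list(cuts) + [len(carriers)]:
                parts.append([carriers[k] for k in order[prev:c]])
                prev = c
            for p_idx, part in enumerate(parts):
                if p_idx == 0:
                    s0, e0 = start, end
                else:
                    s0, e0 = _shift_interval(start, end, rng, params.jitter_mean)
                part_row = np.zeros(n_samples, dtype=np.int8)
                for s in part:
                    part_row[col[s]] = row[col[s]]
                eid = f"{tid}.{p_idx}"
                emitted.append(SVRecord(id=eid, chrom=chrom, start=s0, end=e0,
                                        svtype=svtype, length=e0 - s0 + 1,
                                        pseudo_interval=svtype == "INS"))
                emitted_rows.append(part_row)
                emitted_of[tid].append(eid)
                true_of[eid] = tid

    order = sorted(range(len(emitted)),
                   key=lambda i: (emitted[i].chrom, emitted[i].start, emitted[i].id))
    records = [emitted[i] for i in order]
    values = (np.vstack([emitted_rows[i] for i in order]) if order
              else np.empty((0, n_samples), np.int8))
    matrix = GenotypeMatrix(values=values, samples=list(samples))
    truth = GroundTruth(
        true_records=true_records,
        true_matrix=GenotypeMatrix(values=np.vstack(true_rows), samples=list(samples)),
        emitted_of=emitted_of, true_of=true_of)
    return records, matrix, pedigree, truth


def score_recovery(
    clustering: Clustering, records: list[SVRecord], truth: GroundTruth
) -> tuple[float, float]:
    """(recall, precision) of decomposition recovery.

    Recall: fraction of decomposed true SVs whose emitted records all ended
    up in one merged component.  Precision: fraction of merged components of
    size >= 2 whose members all derive from the same true SV.  Either is 1.0
    when its denominator is empty.
    """
    comp_of: dict[str, int] = {}
    for c_idx, (comp, merged) in enumerate(zip(clustering.components, clustering.merged)):
        for i in comp:
            comp_of[records[i].id] = c_idx if merged else -1 - i

    decomposed = truth.decomposed_ids
    if decomposed:
        hits = 0
        for tid in decomposed:
            comps = {comp_of[eid] for eid in truth.emitted_of[tid]}
            if len(comps) == 1 and next(iter(comps)) >= 0:
                hits += 1
        recall = hits / len(decomposed)
    else:
        recall = 1.0

    big = [c for c, m in zip(clustering.components, clustering.merged) if m and len(c) >= 2]
    if big:
        pure = sum(1 for comp in big
                   if len({truth.true_of[records[i].id] for i in comp}) == 1)
        precision = pure / len(big)
    else:
        precision = 1.0
    return recall, precision


def write_truth_tsv(path: str, truth: GroundTruth) -> None:
    with open(path, "w") as fh:
        fh.write("true_id\temitted_ids\tn_records\n")
        for tid, eids in truth.emitted_of.items():
            fh.write(f"{tid}\t{','.join(eids)}\t{len(eids)}\n")
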