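"""Core data model: SV records, genotype matrices, pedigrees, merging semantics.

The central object is the genotype matrix: one row per structural-variant
(SV) record, one column per sample, entries coded 0 (reference homozygote),
1 (heterozygote), 2 (alternate homozygote).  Merging a set of SV rows is
defined as elementwise summation of their genotype vectors; a pair of rows
is *merging-incompatible* when some sample is non-reference in both, because
the sum would then be ambiguous (it could exceed the diploid range or
conflate two genuinely distinct variants carried by one individual).

Coordinates are VCF-native: 1-based, inclusive on both ends.  Overlap length
between [s1, e1] and [s2, e2] is ``max(0, min(e1, e2) - max(s1, s2) + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

INTERVAL_SVTYPES = ("DEL", "DUP", "INV")
SVTYPES = ("DEL", "DUP", "INV", "INS")


@dataclass(frozen=True)
class SVRecord:
    """One called structural variant.

    ``start``/``end`` are 1-based inclusive genomic positions.  For
    insertions the VCF interval is a point; we synthesize the pseudo-interval
    ``[POS, POS + |SVLEN| - 1]`` so that overlap-based dissimilarity is
    well defined, and mark the record with ``pseudo_interval=True``.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    pseudo_interval: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"SV {self.id}: end {self.end} < start {self.start}")
        if self.length < 1:
            raise ValueError(f"SV {self.id}: non-positive length {self.length}")

    def overlap(self, other: "SVRecord") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class GenotypeMatrix:
    """N SVs x M samples genotype matrix with entries in {0, 1, 2}."""

    values: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype matrix must be 2-dimensional")
        if self.values.shape[1] != len(self.samples):
            raise ValueError("column count does not match sample list")
        if self.values.size and not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("genotype entries must be in {0, 1, 2}")
        self._col = {s: j for j, s in enumerate(self.samples)}

    @property
    def n_svs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def column(self, sample: str) -> int:
        try:
            return self._col[sample]
        except KeyError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def trio_vectors(self, trio: Sequence[str]) -> np.ndarray:
        """N x 3 slice (child, parent1, parent2) for one trio."""
        cols = [self.column(s) for s in trio]
        return self.values[:, cols]


def is_merging_incompatible(v_i: np.ndarray, v_j: np.ndarray) -> bool:
    """True iff some sample is non-reference in both genotype vectors."""
    v_i = np.asarray(v_i)
    v_j = np.asarray(v_j)
    if v_i.shape != v_j.shape:
        raise ValueError("genotype vectors differ in length")
    return bool(np.any((v_i != 0) & (v_j != 0)))


def merge_genotypes(rows: Iterable[int], matrix: GenotypeMatrix) -> np.ndarray:
    """Merge a set of pairwise-compatible SV rows by elementwise summation.

    Raises ``ValueError`` if the rows contain a merging-incompatible pair;
    callers are expected to have checked compatibility first.
    """
    rows = sorted(set(rows))
    if not rows:
        raise ValueError("cannot merge an empty set of rows")
    sub = matrix.values[rows]
    if np.any((sub != 0).sum(axis=0) > 1):
        raise ValueError("rows contain a merging-incompatible pair")
    return sub.sum(axis=0).astype(np.int8)


def rows_pairwise_compatible(rows: Sequence[int], matrix: GenotypeMatrix) -> bool:
    """True iff no sample is non-reference in more than one of the rows."""
    sub = matrix.values[list(rows)]
    return not np.any((sub != 0).sum(axis=0) > 1)


def build_cannot_link(
    matrix: GenotypeMatrix, candidate_pairs: Iterable[tuple[int, int]]
) -> dict[tuple[int, int], bool]:
    """Symmetric cannot-link relation over candidate SV index pairs.

    Returned as a dict keyed by sorted index pairs; a pair maps to True iff
    the two genotype rows are merging-incompatible.
    """
    nz = matrix.values != 0
    out: dict[tuple[int, int], bool] = {}
    for i, j in candidate_pairs:
        a, b = (i, j) if i < j else (j, i)
        out[(a, b)] = bool(np.any(nz[a] & nz[b]))
    return out


# ---------------------------------------------------------------------------
# Pedigree

@dataclass
class Pedigree:
    """Samples, parent-child trios and pairwise relationship coefficients.

    ``trios`` are (child, father, mother) triples — every individual with
    both parents recorded contributes one trio.  ``kinship_pairs`` maps
    unordered within-family sample pairs to the relationship coefficient r
    (twice the kinship coefficient; 0.5 parent-child, 0.25
    grandparent-grandchild, ...).
    """

    samples: list[str]
    trios: list[tuple[str, str, str]]
    families: dict[str, list[str]] = field(default_factory=dict)
    kinship_pairs: dict[frozenset, float] = field(default_factory=dict)

    @property
    def unrelated(self) -> list[str]:
        """Samples in single-member families (no pedigree relationships)."""
        singles = {s for mem in self.families.values() if len(mem) == 1 for s in mem}
        return [s for s in self.samples if s in singles]

    def family_trios(self, family: str) -> list[tuple[str, str, str]]:
        members = set(self.families.get(family, ()))
        return [t for t in self.trios if set(t) <= members]


def _kinship_phi(ind: str, other: str, parents: dict, depth: dict, memo: dict) -> Fraction:
    """Kinship coefficient phi(a, b) by the standard recursive path-counting
    rule, assuming non-inbred founders."""
    key = (ind, other) if ind <= other else (other, ind)
    if key in memo:
        return memo[key]
    if ind == other:
        val = Fraction(1, 2)
    else:
        # recurse on the deeper (younger) individual so ancestors terminate
        a, b = (ind, other) if depth[ind] >= depth[other] else (other, ind)
        pa = parents.get(a)
        if pa is None or depth[a] == 0:
            val = Fraction(0)
        else:
            fa, mo = pa
            val = (_kinship_phi(fa, b, parents, depth, memo)
                   + _kinship_phi(mo, b, parents, depth, memo)) / 2
    memo[key] = val
    return val


def read_pedigree(path: str) -> Pedigree:
    """Read a 6-column whitespace-delimited PED file.

    Trios are rows where both parent identifiers are non-zero; relationship
    coefficients are computed by recursive kinship path counting within each
    family.  A parent named but absent from the file, or a cyclic pedigree,
    raises ``ValueError``.
    """
    samples: list[str] = []
    families: dict[str, list[str]] = {}
    parents: dict[str, tuple[str, str]] = {}
    fam_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 PED columns")
            fam, ind, pat, mat = fields[0], fields[1], fields[2], fields[3]
            if ind in fam_of:
                raise ValueError(f"{path}:{lineno}: duplicate individual {ind!r}")
            samples.append(ind)
            families.setdefault(fam, []).append(ind)
            fam_of[ind] = fam
            if pat != "0" and mat != "0":
                parents[ind] = (pat, mat)
            elif pat != "0" or mat != "0":
                raise ValueError(
                    f"{path}:{lineno}: individual {ind!r} has exactly one parent recorded"
                )
    known = set(samples)
    for ind, (fa, mo) in parents.items():
        for p in (fa, mo):
            if p not in known:
                raise ValueError(f"parent {p!r} of {ind!r} absent from pedigree")

    # generation depth; detects cycles
    depth: dict[str, int] = {}

    def _depth(ind: str, stack: frozenset) -> int:
        if ind in depth:
            return depth[ind]
        if ind in stack:
            raise ValueError(f"cyclic pedigree at individual {ind!r}")
        if ind not in parents:
            depth[ind] = 0
        else:
            fa, mo = parents[ind]
            stack = stack | {ind}
            depth[ind] = 1 + max(_depth(fa, stack), _depth(mo, stack))
        return depth[ind]

    for s in samples:
        _depth(s, frozenset())

    trios = [(c, fa, mo) for c, (fa, mo) in parents.items()]

    memo: dict = {}
    kinship: dict[frozenset, float] = {}
    for members in families.values():
        for a, b in combinations(members, 2):
            r = 2 * _kinship_phi(a, b, parents, depth, memo)
            kinship[frozenset((a, b))] = float(r)
    return Pedigree(samples=samples, trios=trios, families=families,
                    kinship_pairs=kinship)


# ---------------------------------------------------------------------------
# VCF input / output

_GT_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def read_sv_vcf(path: str, min_length: int = 50) -> tuple[list[SVRecord], GenotypeMatrix]:
    """Read SV records and genotypes from a VCF.

    Keeps records with length strictly greater than ``min_length`` (the
    conventional >50 bp definition of a structural variant).  Genotypes map
    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2; missing genotypes are coded as
    reference with an aggregated warning.  BND records and records lacking
    both END and SVLEN are skipped and counted.
    """
    vcf = pysam.VariantFile(path)
    samples = list(vcf.header.samples)
    records: list[SVRecord] = []
    rows: list[list[int]] = []
    n_missing = n_bnd = n_bad = 0
    for rec in vcf:
        svtype = rec.info.get("SVTYPE")
        if svtype is None or svtype == "BND":
            n_bnd += 1
            continue
        try:
            svlen = rec.info.get("SVLEN")
        except ValueError:  # SVLEN not declared in this header
            svlen = None
        if isinstance(svlen, tuple):
            svlen = svlen[0]
        pos = rec.pos
        pseudo = False
        if svtype == "INS":
            if svlen is None:
                n_bad += 1
                continue
            length = abs(int(svlen))
            end = pos + length - 1
            pseudo = True
        else:
            end = rec.stop  # pysam: INFO/END as 1-based inclusive
            if end <= pos and svlen is not None:
                end = pos + abs(int(svlen)) - 1
            if end <= pos and svlen is None:
                n_bad += 1
                continue
            length = end - pos + 1
        if length <= min_length:
            continue
        row = []
        for name in samples:
            gt = rec.samples[name].get("GT")
            if gt is None or any(a is None for a in gt):
                n_missing += 1
                row.append(0)
            else:
                code = _GT_CODE.get(tuple(gt))
                if code is None:
                    raise ValueError(f"{path}: non-biallelic genotype {gt} at {rec.id}")
                row.append(code)
        rid = rec.id or f"sv_{rec.chrom}_{pos}"
        records.append(SVRecord(id=rid, chrom=rec.chrom, start=pos, end=end,
                                svtype=svtype, length=length, pseudo_interval=pseudo))
        rows.append(row)
    if n_missing:
        logger.warning("%d missing genotypes coded as reference", n_missing)
    if n_bnd:
        logger.info("%d BND/untyped records skipped", n_bnd)
    if n_bad:
        logger.warning("%d records lacking both END and SVLEN skipped", n_bad)
    values = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), np.int8)
    return records, GenotypeMatrix(values=values, samples=samples)


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_sv_vcf(
    path: str,
    records: Sequence[SVRecord],
    matrix: GenotypeMatrix,
    extra_info: Sequence[dict] | None = None,
) -> None:
    """Write SV records and genotypes to a multi-sample VCF 4.2 file.

    ``extra_info`` optionally supplies per-record INFO fields (MEMBERS,
    MERGED, STRATEGY) used when materializing merged call sets.
    """
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(r.chrom for r in records):
        header.contigs.add(chrom, length=2_000_000_000)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SVLEN", 1, "Integer", "Length of the variant")
    header.info.add("MEMBERS", ".", "String", "IDs of merged member records")
    header.info.add("MERGED", 1, "Integer", "1 if record is a merge product")
    header.info.add("STRATEGY", 1, "String", "Clustering strategy used")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in matrix.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for i, r in enumerate(records):
            # pysam new_record takes 0-based start; stop carries INFO/END
            rec = out.new_record(contig=r.chrom, start=r.start - 1, stop=r.end,
                                 alleles=("N", f"<{r.svtype}>"))
            rec.id = r.id
            rec.info["SVTYPE"] = r.svtype
            # VCF convention: SVLEN = END - POS for interval types (htslib
            # recomputes END from it); insertion length for INS
            rec.info["SVLEN"] = r.length if r.svtype == "INS" else r.end - r.start
            if extra_info is not None:
                for key, val in extra_info[i].items():
                    rec.info[key] = val
            for j, s in enumerate(matrix.samples):
                g = int(matrix.values[i, j])
                rec.samples[s]["GT"] = ((0, 0), (0, 1), (1, 1))[g]
            out.write(rec)


def write_matrix_tsv(path: str, records: Sequence[SVRecord], matrix: GenotypeMatrix) -> None:
    """Dump the genotype matrix as TSV (one row per SV, one column per sample)."""
    import pandas as pd

    df = pd.DataFrame(matrix.values, columns=matrix.samples)
    df.insert(0, "id", [r.id for r in records])
    df.insert(1, "chrom", [r.chrom for r in records])
    df.insert(2, "start", [r.start for r in records])
    df.insert(3, "end", [r.end for r in records])
    df.insert(4, "svtype", [r.svtype for r in records])
    df.to_csv(path, sep="\t", index=False)
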