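# Methods

## Data model

The unit of analysis is a multi-sample SV call set: N records (chromosome,
1-based inclusive interval, type ∈ {DEL, DUP, INV, INS}, length > 50 bp)
and an N×M genotype matrix with entries 0 (reference homozygote), 1
(heterozygote), 2 (alternate homozygote). Merging a set of rows means
elementwise summation of their genotype vectors. Two rows are
*merging-incompatible* when some sample is non-reference in both: the sum
would be ambiguous (and can leave the diploid range), and the two records
demonstrably represent different variants in that sample. Incompatibility
is the single hard constraint every strategy must respect.

Coordinate conventions: intervals are closed, overlap length is
`max(0, min(e1,e2) − max(s1,s2) + 1)`. Insertions have a point interval in
VCF; we give them the pseudo-interval `[POS, POS + |SVLEN| − 1]` (flagged
`pseudo_interval`) so overlap dissimilarity is defined. Missing genotypes
are read as reference with an aggregated warning — the conservative choice,
since it can never create a spurious incompatibility. BND records and
records lacking both END and SVLEN are skipped and counted. All samples
are treated as diploid everywhere, including sex chromosomes; hemizygous
male chrX/Y calls are read as heterozygous, a documented caveat.

## Dissimilarities and clustering

D₁ = 1 − overlap/max(length) ∈ [0,1]; D₂ = max breakpoint distance in bp
(a true metric). Clusters are connected components of the threshold graph
(edges where D ≤ D_max, same chromosome and type only). Candidate edges are
generated by a sorted sweep on (chrom, type, start) — for D₂ a start-window
of D_max, for D₁ the overlap requirement start ≤ end of the anchor — which
provably misses no edge and avoids the all-pairs quadratic scan; tests
verify equivalence against an all-pairs reference up to 200 SVs.

**Trivial strategy**: a component containing an incompatible pair is left
entirely unmerged. **Corrected strategy**: such a component is re-split at
the maximal threshold D < D_max whose induced sub-components are all
conflict-free. Candidate thresholds are the realized pairwise
dissimilarities inside the component (< D_max), scanned descending; the
sub-component structure can only change at those values, so the maximum is
exact with finite work. If two incompatible records sit at identical
coordinates no non-negative threshold separates them; the component then
falls back to singletons. **Deterministic output**: components are
processed in (chrom, start, ID) order and all tie-breaks are lexicographic,
so results are bit-reproducible.

A merged record spans min(start)–max(end) of its members, takes the
lexicographically smallest member ID, and lists members in INFO/MEMBERS;
per-sample allele counts are conserved exactly between input and output
matrices.

## Trio-constrained clustering

A decomposed SV — one true variant reported as 2–3 records whose carrier
sets partition the true carriers — restricted to a (child, parent₁,
parent₂) trio yields non-trivial vectors with disjoint support summing to a
Mendelian-consistent configuration. Exhaustive enumeration over {0,1,2}³
gives 26 such unordered pairs and 7 triplets; a fourth disjoint-support
non-trivial vector cannot exist (only three positions), which bounds the
search. Consistency follows the diploid transmission rule: a parent with
genotype 0/1/2 can transmit {0}/{0,1}/{1} alternate alleles; 15 of the 27
trio configurations are consistent.

The pipeline:

1. **Combinatorial search** per trio over threshold-graph edges (pairs) and
   triangles (triplets) whose trio-restricted vectors match a mergeable
   signature, requiring (a) compatibility over *all* samples and (b) every
   member pair within D_max. Identical member sets found in several trios
   accumulate their supporting trios.
2. **Reduction** of overlapping groups: groups sharing an SV form an
   intersection graph; per connected component, groups are accepted
   greedily by descending trio support (seeded random tie-break), each
   tested for compatibility with the already-accepted members of the
   component and for Mendelian consistency of the merged vector in every
   trio (trivial merged vectors count as consistent). All accepted groups
   of one intersection component form a single reduced component.
3. **Constrained agglomeration**: reduced components are pre-linked
   (must-link); remaining candidate pairs are processed in ascending
   dissimilarity (ties in (chrom, start, ID) order), accepting a link only
   if the union contains no incompatible pair — tested in O(M) via
   per-cluster carrier masks, which is exactly the pairwise cannot-link
   check because clusters are conflict-free by induction. The loop stops
   when no cross-cluster pair at D ≤ D_max remains, making the constrained
   strategy comparable to the unconstrained ones at equal D_max.

One seeded generator (numpy PCG64) drives all tie-breaks, consumed in
deterministic iteration order; a fixed seed gives bit-identical output.

## Quality metrics

* **f_MEI**: fraction of Mendelian-erroneous configurations among SVs
  *non-trivial in the trio*. The denominator choice matters: all-reference
  trios carry no inheritance information, so including them would only
  dilute the signal; 0/0 is reported as 0 with a warning. Every
  (child, father, mother) triple in the pedigree is evaluated
  independently, including middle-generation individuals who are children
  in one trio and parents in another.
* **N_ic**: merged components (size ≥ 2) containing ≥ 1 Mendelian-erroneous
  member whose merged trio vector is non-trivial and consistent.
  Singletons cannot "result from merging" and are excluded. **N_cc** (the
  converse — error-free members merging into an error) is implemented for
  completeness, but exhaustive search shows no 2–3 disjoint-support
  consistent vectors sum to an inconsistent configuration, so N_cc is
  structurally zero at the trio level; a test documents this.
* **Kinship separation**: any pair→estimate map is accepted; the built-in
  estimator is the proportion of shared alleles
  S_xy = mean over informative loci of (min(g,h) + min(2−g,2−h))/2,
  excluding loci monomorphic across the cohort. Categories are the
  distinct pedigree relationship coefficients r (computed by recursive
  kinship path counting, assuming non-inbred founders). A pair counts as
  separated when its estimate lies strictly between the neighboring
  categories' extreme values; s_i = 1 − L_i/n_pairs_i and ⟨s⟩ is the
  unweighted category mean. The per-category pair count is used as the
  denominator because the error rate must live in [0,1]; categories with
  fewer than two pairs are skipped. More elaborate frequency-weighted
  estimators (e.g. Loiselle) can be plugged in through the same map
  interface; none is bundled.
* **f_HWeq**: per polymorphic SV among unrelated samples, a 1-df Pearson
  χ² without continuity correction against p²/2pq/q², Bonferroni-corrected
  over the tested SVs; f_HWeq is the fraction with corrected p ≥ α
  (default 0.05). Monomorphic loci are untestable and excluded from both
  numerator and denominator.

## Randomization null model

Rows of the genotype matrix are permuted uniformly within each SV type
(genome-wide, not per chromosome), leaving coordinates fixed. At any
threshold this preserves the cluster size distribution while destroying
genotype–position association, so decomposition signatures in the ensemble
arise only by chance. The ensemble default is 10 replicates, seeded
`seed + k`; randomization is applied before the correction step so
incompatible pairs are still removed by the strategy under evaluation (the
corrected strategy by default). Envelopes are pointwise min/max across
replicates.

## Synthetic data generator

The generator emulates the study conditions the framework targets:

* **Pedigree**: three-generation families (a grandparental couple, their
  children married to founder spouses, grandchildren) plus unrelated
  individuals. Defaults mirror a cohort with families of 10 and 12 members
  and 102 unrelated samples; tests use smaller cohorts (one 5-member
  family with two trios, 25 unrelated; sizes stated per test).
* **Genotypes**: founder alleles Bernoulli(q) with q ~ Beta(0.5, 3)
  (skewed toward rare variants, as SV frequency spectra are), gene-dropped
  through the pedigree — the true matrix is Mendelian-error-free by
  construction — and Hardy–Weinberg draws for unrelated samples.
* **Loci**: types weighted DEL 0.5 / DUP 0.2 / INV 0.15 / INS 0.15,
  lengths log-uniform on [51 bp, 100 kb], positions uniform over 2×10 Mb
  chromosomes.
* **Errors**: with probability `p_decompose` (default 0.2) a variant's
  carriers are split into 2 or 3 non-empty subsets (2:1 odds, echoing the
  pairs-dominant combinatorics), each emitted at a breakpoint-shifted
  position; otherwise a single record is emitted, jittered with
  probability `p_jitter` (default 0.2). Offsets are symmetric non-zero
  geometric (mean 30 bp) applied independently to both breakpoints,
  truncated to keep length > 50 bp.
* **Hotspots**: with probability `p_hotspot` (default 0.15) a true SV is
  *recurrent* — placed with near-identical breakpoints (geometric offsets,
  mean 50 bp) to an earlier SV of the same type, emulating repeat-mediated
  recurrent rearrangements. Recurrent SVs often share carriers, creating
  genuine merging-incompatible pairs inside clusters; without this process
  conflicts essentially never occur and all strategies coincide.

Loci are independent (no linkage disequilibrium), error processes are
independent of allele frequency, and no read-level artifacts (genotyping
error, missing calls, coverage effects) are modeled. Passing tests
therefore demonstrate correctness of the algorithms and the direction of
the method ranking under the modeled error processes, not absolute error
rates on real cohorts.

Recovery is scored against ground truth: recall = fraction of decomposed
true SVs whose fragments end in one merged cluster; precision = fraction
of merged clusters (size ≥ 2) whose members share one true SV.

## Problem sizes and numerical choices

Library tests run on instances up to 200 SVs against brute-force
references; end-to-end checks use 500 true SVs and 30 samples, with the
null-model comparison at 10 replicates over 6-point grids per measure —
sizes chosen so the full suite exercises every code path in seconds while
leaving clear margins between the compared quantities. Default threshold
grids are 0.05–0.95 (step 0.05) for D₁ and 50–1000 bp (step 50) for D₂.
All randomness flows from explicit integer seeds; no global RNG state is
used. Dissimilarities are exact rationals in floating point (counts and
integer distances), so threshold comparisons involve no tolerance issues.

## Known limitations

* Genotype likelihoods are ignored; merging acts on hard genotype calls.
* The greedy group reduction is order-dependent by design (trio-support
  ranking with seeded tie-breaks); it does not revisit rejected groups.
* Hemizygosity and multi-allelic records are flattened to the 0/1/2 model.
* The generator's precision ceiling: recurrent SVs with disjoint carrier
  sets are genotype-indistinguishable from decompositions, so no
  genotype-based method can reach precision 1 on hotspot-containing data.
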