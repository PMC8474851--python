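# svmerge

Merging multi-sample structural-variant (SV) call sets under breakpoint
uncertainty.

Short-read SV callers cannot pinpoint breakpoints exactly, so one true
variant shared by several individuals is often reported at slightly
different coordinates in each sample. Population analyses that naively
stack per-sample calls then see many spurious "distinct" variants. The
usual remedy is to cluster nearby same-type SVs and merge each cluster
into one record — but the choice of dissimilarity measure, threshold and
conflict-handling strategy changes the result substantially, and is rarely
validated.

`svmerge` implements and benchmarks this whole space:

* **Two dissimilarity measures** between SV intervals g₁, g₂ of the same
  type on the same chromosome:
  * overlap-based **D₁ = 1 − |g₁ ∩ g₂| / max(|g₁|, |g₂|)** (0 identical,
    1 disjoint);
  * breakpoint-distance **D₂ = max(|start₁ − start₂|, |end₁ − end₂|)** in bp.
  Clusters are connected components of the graph linking pairs with
  D ≤ D_max.
* **Three clustering strategies.** Merging is genotype summation over a
  cluster's rows of the N×M genotype matrix (entries 0/1/2). Two rows are
  *merging-incompatible* if some sample is non-reference in both — such a
  pair must never be merged. The *trivial* strategy refuses to merge any
  conflicted cluster; the *corrected* strategy re-splits a conflicted
  cluster at the maximal sub-threshold D < D_max that removes all conflicts;
  the *constrained* strategy additionally exploits parent–child trios: a
  decomposed SV (one true variant reported as 2–3 records with
  complementary carriers) leaves a characteristic trio signature — a set of
  non-trivial genotype vectors (child, parent₁, parent₂) with disjoint
  support whose sum is Mendelian-consistent. Exactly **26 such pairs and 7
  triplets** exist. The constrained method finds them combinatorially,
  reduces overlapping candidates to a disjoint accepted set, and runs
  cannot-link constrained agglomerative clustering seeded with the accepted
  groups as must-link components.
* **Dataset-quality metrics**: per-trio Mendelian-error fraction f_MEI;
  N_ic, the count of merged clusters that contained a Mendelian error yet
  merged into a consistent configuration; kinship-category separation ⟨s⟩
  of the shared-allele estimator S_xy; and the fraction of SVs in
  Hardy–Weinberg equilibrium among unrelated samples (χ², Bonferroni).
* **A randomization null model** (genotype rows reshuffled within SV type)
  to test whether the decomposed-SV pattern is a real feature of the data.
* **A synthetic-data generator**: gene-dropping through three-generation
  pedigrees plus unrelated individuals, with controlled breakpoint jitter,
  decomposition and recurrent-hotspot errors, and full ground truth.

## Worked example

```python
import numpy as np
from svmerge import (SimulationParams, PedigreeSpec, FamilySpec, simulate,
                     DissimilarityParams, trivial_strategy, corrected_strategy,
                     constrained_clustering, materialize, trio_f_mei,
                     score_recovery)

params = SimulationParams(
    n_true_svs=500,
    pedigree_spec=PedigreeSpec(families=[FamilySpec(1, 1)], n_unrelated=25),
    p_decompose=0.2, seed=1)
records, matrix, pedigree, truth = simulate(params)
print(f"{len(records)} records, {matrix.n_samples} samples, "
      f"{len(truth.decomposed_ids)} decomposed true SVs")

d = DissimilarityParams(measure="d2", d_max=200)
for name, cl in [
        ("trivial", trivial_strategy(matrix, records, d)),
        ("corrected", corrected_strategy(matrix, records, d)),
        ("constrained", constrained_clustering(matrix, records, pedigree, d, seed=1))]:
    _, merged, _ = materialize(cl, records, matrix)
    f_mei = np.mean([trio_f_mei(merged, t) for t in pedigree.trios])
    recall, precision = score_recovery(cl, records, truth)
    print(f"{name:12s} f_MEI={f_mei:.4f}  recall={recall:.3f}  precision={precision:.3f}")
```

prints

```
601 records, 30 samples, 73 decomposed true SVs
trivial      f_MEI=0.0030  recall=0.918  precision=0.698
corrected    f_MEI=0.0030  recall=0.945  precision=0.649
constrained  f_MEI=0.0000  recall=0.973  precision=0.643
```

500 true SVs became 601 records because 73 of them were decomposed into
2–3 fragments. At D₂ ≤ 200 bp the trivial strategy reassembles 91.8% of
decompositions, the corrected strategy 94.5%, and the constrained strategy
97.3% while also driving the trio Mendelian-error fraction to zero —
recovering the method ranking the framework is designed to expose.
Precision dips below 1 for all strategies because recurrent hotspot SVs
with compatible genotypes are indistinguishable from decompositions at the
genotype level.

The same pipeline is available from the shell:

```bash
svmerge simulate --config config.yaml --out sim/
svmerge cluster --strategy constrained --measure d2 --dmax 200 --seed 1 \
    --vcf sim/calls.vcf --ped sim/pedigree.ped --out merged.vcf
svmerge sweep --vcf sim/calls.vcf --ped sim/pedigree.ped --out sweep.tsv
svmerge nullmodel --vcf sim/calls.vcf --ped sim/pedigree.ped --replicates 10 \
    --seed 1 --out null.tsv
```

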