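"""Trio-constrained clustering: group search, reduction, agglomeration."""

import numpy as np

from svmerge import (DissimilarityParams, GenotypeMatrix, Pedigree,
                     constrained_clustering, corrected_strategy, find_sv_groups,
                     reduce_to_disjoint, score_recovery)
from svmerge.constrained import SVGroup
from conftest import mkrec, random_instance
from oracles import has_incompatible_pair


def trio_pedigree(child="C", p1="F", p2="M", extra=()):
    samples = [child, p1, p2, *extra]
    fams = {"FAM1": [child, p1, p2]}
    for s in extra:
        fams[s] = [s]
    return Pedigree(samples=samples, trios=[(child, p1, p2)], families=fams,
                    kinship_pairs={frozenset((child, p1)): 0.5,
                                   frozenset((child, p2)): 0.5,
                                   frozenset((p1, p2)): 0.0})


def mat(rows, n_samples=None):
    arr = np.array(rows, dtype=np.int8)
    n = n_samples or arr.shape[1]
    return GenotypeMatrix(values=arr, samples=["C", "F", "M"] + [f"U{k}" for k in range(n - 3)])


D2_50 = DissimilarityParams(measure="d2", d_max=50)


class TestFindGroups:
    def test_worked_example_pair_found(self):
        recs = [mkrec(id="a", start=100, end=200), mkrec(id="b", start=120, end=220)]
        m = mat([[2, 1, 0], [0, 0, 1]])
        groups = find_sv_groups(m, recs, trio_pedigree(), D2_50)
        assert len(groups) == 1
        assert groups[0].members == frozenset((0, 1))
        assert groups[0].trios_detected_in == {0}

    def test_shared_nontrio_carrier_rejects_group(self):
        recs = [mkrec(id="a", start=100, end=200), mkrec(id="b", start=120, end=220)]
        m = mat([[2, 1, 0, 1], [0, 0, 1, 1]])  # sample U0 carries both
        groups = find_sv_groups(m, recs, trio_pedigree(extra=("U0",)), D2_50)
        assert groups == []

    def test_distance_above_threshold_rejects_group(self):
        recs = [mkrec(id="a", start=100, end=200), mkrec(id="b", start=500, end=600)]
        m = mat([[2, 1, 0], [0, 0, 1]])
        assert find_sv_groups(m, recs, trio_pedigree(), D2_50) == []

    def test_triplet_found(self):
        # (2,1,1) decomposed three ways: (2,0,0) is not usable alone but the
        # pattern {(0,1,0),(0,0,1),(2,0,0)} sums to the consistent (2,1,1)
        recs = [mkrec(id="a", start=100, end=200),
                mkrec(id="b", start=110, end=210),
                mkrec(id="c", start=120, end=220)]
        m = mat([[2, 0, 0], [0, 1, 0], [0, 0, 1]])
        groups = find_sv_groups(m, recs, trio_pedigree(), D2_50)
        assert frozenset((0, 1, 2)) in {g.members for g in groups}

    def test_same_group_in_two_trios_accumulates(self):
        samples = ["C1", "F1", "M1", "C2", "F2", "M2"]
        ped = Pedigree(samples=samples,
                       trios=[("C1", "F1", "M1"), ("C2", "F2", "M2")],
                       families={"FAM1": samples[:3], "FAM2": samples[3:]},
                       kinship_pairs={})
        recs = [mkrec(id="a", start=100, end=200), mkrec(id="b", start=120, end=220)]
        arr = np.array([[2, 1, 0, 2, 1, 0], [0, 0, 1, 0, 0, 1]], dtype=np.int8)
        m = GenotypeMatrix(values=arr, samples=samples)
        groups = find_sv_groups(m, recs, ped, D2_50)
        assert len(groups) == 1
        assert groups[0].trios_detected_in == {0, 1}


class TestReduce:
    def test_disjoint_groups_both_retained(self):
        m = mat([[2, 1, 0], [0, 0, 1], [0, 1, 0], [0, 0, 1]])
        groups = [SVGroup(frozenset((0, 1)), {0}), SVGroup(frozenset((2, 3)), {0})]
        kept = reduce_to_disjoint(groups, m, trio_pedigree(), seed=0)
        assert {g.members for g in kept} == {frozenset((0, 1)), frozenset((2, 3))}
        assert len({g.component_id for g in kept}) == 2

    def test_overlap_resolved_by_trio_support(self):
        m = mat([[2, 1, 0], [0, 0, 1], [0, 0, 1]])
        groups = [SVGroup(frozenset((0, 1)), {0, 1, 2}), SVGroup(frozenset((0, 2)), {0})]
        kept = reduce_to_disjoint(groups, m, trio_pedigree(), seed=0)
        assert {g.members for g in kept} == {frozenset((0, 1))}

    def test_tie_broken_by_seed_keeps_exactly_one(self):
        m = mat([[2, 1, 0], [0, 0, 1], [0, 0, 1]])
        groups = [SVGroup(frozenset((0, 1)), {0}), SVGroup(frozenset((0, 2)), {0})]
        seen = set()
        for seed in range(10):
            kept = reduce_to_disjoint(groups, m, trio_pedigree(), seed=seed)
            assert len(kept) == 1
            seen.add(next(iter(kept)).members)
            # same seed, same choice
            again = reduce_to_disjoint(groups, m, trio_pedigree(), seed=seed)
            assert kept[0].members == again[0].members
        assert len(seen) == 2  # both choices occur across seeds

    def test_mendelian_test_rejects_bad_union(self):
        """A group whose merged vector is inconsistent in another trio is
        dropped during reduction."""
        samples = ["C1", "F1", "M1", "C2", "F2", "M2"]
        ped = Pedigree(samples=samples,
                       trios=[("C1", "F1", "M1"), ("C2", "F2", "M2")],
                       families={"FAM1": samples[:3], "FAM2": samples[3:]},
                       kinship_pairs={})
        # consistent (2,1,1) pattern in trio 1, but the merged vector is the
        # Mendelian error (1,0,0) in trio 2
        arr = np.array([[2, 1, 0, 1, 0, 0], [0, 0, 1, 0, 0, 0]], dtype=np.int8)
        m = GenotypeMatrix(values=arr, samples=samples)
        groups = [SVGroup(frozenset((0, 1)), {0})]
        assert reduce_to_disjoint(groups, m, ped, seed=0) == []


class TestConstrainedClustering:
    def test_matches_corrected_when_constraints_inactive(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            records, matrix = random_instance(rng, n_svs=15)
            # remove all conflicts so cannot-link and groups are inert
            vals = np.where(np.cumsum(matrix.values != 0, axis=0) > 1, 0,
                            matrix.values).astype(np.int8)
            matrix = GenotypeMatrix(values=vals, samples=matrix.samples)
            ped = Pedigree(samples=matrix.samples, trios=[("S0", "S1", "S2")],
                           families={"FAM1": matrix.samples[:3]}, kinship_pairs={})
            params = DissimilarityParams(measure="d2", d_max=150)
            cc = constrained_clustering(matrix, records, ped, params, seed=0)
            co = corrected_strategy(matrix, records, params)
            assert cc.components == co.components

    def test_group_plus_third_compatible_sv(self):
        recs = [mkrec(id="a", start=100, end=200),
                mkrec(id="b", start=120, end=220),
                mkrec(id="c", start=140, end=240)]
        m = mat([[2, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])
        ped = trio_pedigree(extra=("U0",))
        cl = constrained_clustering(m, recs, ped, D2_50, seed=0)
        assert cl.components == [(0, 1, 2)]

    def test_cannot_link_dominates_distance(self):
        # a-b nearest but incompatible; b-c is the next candidate
        recs = [mkrec(id="a", start=100, end=200),
                mkrec(id="b", start=101, end=201),
                mkrec(id="c", start=140, end=240)]
        m = mat([[1, 0, 0], [1, 0, 0], [0, 1, 0]])
        cl = constrained_clustering(m, recs, trio_pedigree(), D2_50, seed=0)
        assert ((1, 2) in cl.components or (0, 2) in cl.components)
        assert all(not has_incompatible_pair(c, m) for c in cl.components)

    def test_no_cannot_link_pair_in_output(self):
        rng = np.random.default_rng(33)
        for _ in range(30):
            records, matrix = random_instance(rng, n_svs=25)
            ped = Pedigree(samples=matrix.samples, trios=[("S0", "S1", "S2")],
                           families={"FAM1": matrix.samples[:3]}, kinship_pairs={})
            cl = constrained_clustering(matrix, records, ped,
                                        DissimilarityParams(measure="d2", d_max=200),
                                        seed=int(rng.integers(100)))
            for comp in cl.components:
                assert not has_incompatible_pair(comp, matrix)

    def test_seed_reproducibility(self, small_simulation, d2_params):
        records, matrix, ped, _ = small_simulation
        a = constrained_clustering(matrix, records, ped, d2_params, seed=7)
        b = constrained_clustering(matrix, records, ped, d2_params, seed=7)
        assert a.components == b.components

    def test_dominates_corrected_on_decomposed_data(self, small_simulation, d2_params):
        """Constrained clustering reassembles at least as many injected
        decompositions as the corrected strategy at the same threshold."""
        records, matrix, ped, truth = small_simulation
        cc = constrained_clustering(matrix, records, ped, d2_params, seed=1)
        co = corrected_strategy(matrix, records, d2_params)
        rec_cc, _ = score_recovery(cc, records, truth)
        rec_co, _ = score_recovery(co, records, truth)
        assert rec_cc >= rec_co
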