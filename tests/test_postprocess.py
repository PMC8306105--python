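"""Contact maps, top-1000 filter, Jaccard clustering, density ranking."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgdock import (
    ContactMap,
    complete_link_cluster,
    compute_contact_map,
    contact_count_filter,
    jaccard_distance,
    rank_and_select,
)
from cgdock.cg_model import pseudo_atoms_from_xyz
from cgdock.fixtures import extended_chain


def gly_chain(n, origin, axis=0):
    """Straight poly-Gly chain: side-chain centres coincide with the Ca
    trace, so inter-chain sc distances are controlled exactly."""
    xyz = np.zeros((n, 3))
    xyz[:, axis] = 3.8 * np.arange(n)
    return xyz + np.asarray(origin, float)


def cm(pairs, model_id=0, energy=0.0):
    return ContactMap(frozenset(pairs), model_id=model_id, energy=energy)


class TestComputeContactMap:
    def test_cutoff_is_inclusive_six_angstrom(self):
        rec = gly_chain(5, [0, 0, 0])
        lig_in = gly_chain(5, [0, 5.9, 0])
        lig_out = gly_chain(5, [0, 6.1, 0])
        seq = "G" * 5
        inside = compute_contact_map(rec, seq, lig_in, seq)
        outside = compute_contact_map(rec, seq, lig_out, seq)
        assert inside.contacts == frozenset((i, i) for i in range(5))
        assert outside.contacts == frozenset()

    def test_separated_molecules_have_empty_map(self):
        rec = gly_chain(5, [0, 0, 0])
        lig = gly_chain(5, [0, 30.0, 0])
        assert len(compute_contact_map(rec, "G" * 5, lig, "G" * 5)) == 0

    def test_matches_bruteforce_loop(self, toy):
        got = compute_contact_map(toy.rec_ref, toy.rec_seq, toy.lig_ref, toy.lig_seq)
        rsc = pseudo_atoms_from_xyz(toy.rec_ref, toy.rec_seq).sc
        lsc = pseudo_atoms_from_xyz(toy.lig_ref, toy.lig_seq).sc
        expect = set()
        for i in range(len(rsc)):
            for j in range(len(lsc)):
                if np.linalg.norm(rsc[i] - lsc[j]) <= 6.0:
                    expect.add((i, j))
        assert got.contacts == expect


class TestContactCountFilter:
    def test_keeps_largest_counts(self):
        maps = [cm({(0, k) for k in range(c)}, model_id=c) for c in (5, 4, 3, 2, 1)]
        kept = contact_count_filter(maps, keep=2)
        assert [len(m) for m in kept] == [5, 4]

    def test_ten_thousand_in_thousand_out(self):
        rng = np.random.default_rng(0)
        maps = [cm({(0, int(k)) for k in rng.integers(0, 40, size=rng.integers(0, 12))},
                   model_id=i) for i in range(10_000)]
        kept = contact_count_filter(maps, keep=1000)
        assert len(kept) == 1000
        threshold = min(len(m) for m in kept)
        dropped_max = max(len(m) for m in maps if m.model_id not in
                          {k.model_id for k in kept})
        assert dropped_max <= threshold

    def test_all_empty_retained_by_tiebreak(self):
        maps = [cm(set(), model_id=i, energy=float(-i)) for i in range(5)]
        kept = contact_count_filter(maps, keep=3)
        assert [m.model_id for m in kept] == [4, 3, 2]  # lower energy first

    def test_fewer_than_keep_warns_and_keeps_all(self):
        maps = [cm({(0, 0)}, model_id=i) for i in range(3)]
        with pytest.warns(UserWarning):
            assert len(contact_count_filter(maps, keep=10)) == 3


class TestJaccard:
    def test_identical_nonempty_is_zero(self):
        assert jaccard_distance(cm({(1, 2)}), cm({(1, 2)})) == 0.0

    def test_disjoint_nonempty_is_one(self):
        assert jaccard_distance(cm({(1, 2)}), cm({(3, 4)})) == 1.0

    def test_half_overlap(self):
        assert jaccard_distance(cm({(1, 2), (3, 4)}), cm({(1, 2)})) == 0.5

    def test_both_empty_is_zero_by_convention(self):
        assert jaccard_distance(cm(set()), cm(set())) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        def rand_map():
            return cm({(int(i), int(j)) for i, j in
                       rng.integers(0, 6, size=(rng.integers(0, 8), 2))})
        a, b, c = rand_map(), rand_map(), rand_map()
        assert jaccard_distance(a, c) <= (
            jaccard_distance(a, b) + jaccard_distance(b, c) + 1e-12)

    @given(
        a=st.frozensets(st.tuples(st.integers(0, 5), st.integers(0, 5)), max_size=10),
        b=st.frozensets(st.tuples(st.integers(0, 5), st.integers(0, 5)), max_size=10),
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_metric_axioms(self, a, b):
        d = jaccard_distance(cm(a), cm(b))
        assert 0.0 <= d <= 1.0
        assert d == jaccard_distance(cm(b), cm(a))
        assert (d == 0.0) == (a == b)


class TestCompleteLinkClustering:
    def test_two_well_separated_pairs(self):
        # brute-force over all 2-partitions of 4 items confirms the split
        maps = [
            cm({(0, 0), (0, 1)}, 0), cm({(0, 0), (0, 2)}, 1),
            cm({(9, 9), (9, 8)}, 2), cm({(9, 9), (9, 7)}, 3),
        ]
        got = complete_link_cluster(maps, n_clusters=2)
        assert sorted(map(tuple, got)) == [(0, 1), (2, 3)]
        # oracle: the partition minimising the maximum intra-cluster distance
        def max_intra(groups):
            worst = 0.0
            for g in groups:
                for x, y in itertools.combinations(g, 2):
                    worst = max(worst, jaccard_distance(maps[x], maps[y]))
            return worst
        best = min(
            ([list(g1), [i for i in range(4) if i not in g1]]
             for r in range(1, 3) for g1 in itertools.combinations(range(4), r)),
            key=max_intra,
        )
        assert sorted(map(tuple, (sorted(g) for g in best))) == [(0, 1), (2, 3)]

    def test_identical_maps_form_single_cluster(self):
        maps = [cm({(1, 1)}, i) for i in range(6)]
        got = complete_link_cluster(maps, distance_threshold=0.5)
        assert got == [[0, 1, 2, 3, 4, 5]]

    def test_singletons_when_n_clusters_equals_n(self):
        maps = [cm({(i, i)}, i) for i in range(5)]
        got = complete_link_cluster(maps, n_clusters=5)
        assert sorted(map(tuple, got)) == [(0,), (1,), (2,), (3,), (4,)]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(1)
        maps = [cm({(int(i), int(j)) for i, j in rng.integers(0, 5, size=(4, 2))}, k)
                for k in range(12)]
        a = complete_link_cluster(maps, n_clusters=3)
        shuffled = list(maps)
        rng.shuffle(shuffled)
        b = complete_link_cluster(shuffled, n_clusters=3)
        assert sorted(map(tuple, a)) == sorted(map(tuple, b))


class TestRankAndSelect:
    def test_density_formula(self):
        # five members, average pairwise distance 0.25 -> density 20
        base = {(0, k) for k in range(6)}
        variants = [base, base - {(0, 0)}, base - {(0, 1)}, base - {(0, 2)},
                    base - {(0, 3)}]
        maps = [cm(v, i) for i, v in enumerate(variants)]
        dists = [jaccard_distance(a, b) for a, b in itertools.combinations(maps, 2)]
        clusters = rank_and_select([[0, 1, 2, 3, 4]], maps, k=1)
        assert clusters[0].density == pytest.approx(5.0 / np.mean(dists))

    def test_singleton_density_zero_and_ranked_last(self):
        maps = [cm({(0, 0)}, 0), cm({(0, 0), (0, 1)}, 1), cm({(0, 0), (0, 2)}, 2)]
        got = rank_and_select([[0], [1, 2]], maps, k=2)
        assert got[0].members == [1, 2] and got[0].density > 0
        assert got[1].members == [0] and got[1].density == 0.0

    def test_orders_by_density_descending(self):
        tight = [cm({(0, 0), (0, 1)}, i) for i in (0, 1)]          # distance 0
        loose = [cm({(1, 0)}, 2), cm({(2, 0)}, 3)]                 # distance 1
        maps = tight + loose
        got = rank_and_select([[2, 3], [0, 1]], maps, k=2)
        assert got[0].members == [0, 1]
        assert got[0].density >= got[1].density

    def test_representative_minimises_summed_distance(self):
        centre = {(0, k) for k in range(4)}
        maps = [cm(centre, 0), cm(centre - {(0, 1)}, 1), cm(centre | {(5, 5)}, 2)]
        got = rank_and_select([[0, 1, 2]], maps, k=1)
        assert got[0].representative == 0
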