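import numpy as np
import pytest
from hypothesis import given, strategies as st

from moaclust import (
    ClusterSet,
    DescriptorSet,
    SimilarityMatrix,
    avg_self_similarity,
    choose_cluster_count,
    cluster_centre,
    cluster_set_similarity,
    partition,
    pick_biggest_drop,
    select_centers,
)
from conftest import random_similarity_matrix


# --- independent literal re-implementation of the greedy rules (oracle) ---

def brute_select(values, n_max, seed_idx):
    chosen = [seed_idx]
    n = len(values)
    while len(chosen) < n_max:
        best, best_val = None, None
        for i in range(n):
            if i in chosen:
                continue
            v = max(values[i][j] for j in chosen)
            if best_val is None or v < best_val:  # first minimum = lowest index
                best, best_val = i, v
        chosen.append(best)
    return chosen


def brute_assign(values, chosen):
    assign = {}
    for i in range(len(values)):
        best = 0
        for k in range(1, len(chosen)):
            if values[i][chosen[k]] > values[i][chosen[best]]:  # strict: ties stay early
                best = k
        assign[i] = best
    for k, c in enumerate(chosen):
        assign[c] = k
    return assign


class TestSelectCenters:
    def test_single_center_is_the_seed(self, toy_sim):
        assert select_centers(toy_sim, 1, "A") == ["A"]

    def test_exhaustion_returns_everything(self, toy_sim):
        centers = select_centers(toy_sim, 4, "A")
        assert sorted(centers) == ["A", "B", "C", "D"]
        assert centers[0] == "A"

    def test_second_center_is_most_dissimilar(self, toy_sim):
        # C minimizes its similarity to A (0.2 < 0.3 < 0.9)
        assert select_centers(toy_sim, 2, "A") == ["A", "C"]

    def test_nested_prefixes(self, toy_sim):
        full = select_centers(toy_sim, 4, "B")
        for n in range(1, 5):
            assert select_centers(toy_sim, n, "B") == full[:n]

    def test_n_max_out_of_range(self, toy_sim):
        with pytest.raises(ValueError):
            select_centers(toy_sim, 5, "A")
        with pytest.raises(ValueError):
            select_centers(toy_sim, 0, "A")


class TestPartition:
    def test_toy_partition(self, toy_sim):
        cs = partition(toy_sim, ["A", "C"])
        assert cs.assignment == {"A": 0, "B": 0, "C": 1, "D": 1}

    def test_all_centers_gives_singletons(self, toy_sim):
        cs = partition(toy_sim, ["A", "B", "C", "D"])
        assert cs.n_clusters == 4
        assert all(len(m) == 1 for m in cs.clusters())

    def test_tie_goes_to_earlier_center(self):
        m = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.2], [0.5, 0.2, 1.0]])
        sim = SimilarityMatrix(("X", "Y", "Z"), m, DescriptorSet.ECFP4)
        cs = partition(sim, ["Y", "Z"])  # X equally similar to both
        assert cs.assignment["X"] == 0

    def test_empty_centers_rejected(self, toy_sim):
        with pytest.raises(ValueError):
            partition(toy_sim, [])


class TestAvgSelfSimilarity:
    def test_all_singletons_is_one(self, toy_sim):
        cs = partition(toy_sim, ["A", "B", "C", "D"])
        assert avg_self_similarity(cs, toy_sim) == 1.0

    def test_two_pair_clusters(self, toy_sim):
        cs = partition(toy_sim, ["A", "C"])  # {A,B}, {C,D}
        assert avg_self_similarity(cs, toy_sim) == pytest.approx((0.9 + 0.8) / 2)

    def test_single_cluster_mean_of_all_pairs(self, toy_sim):
        cs = partition(toy_sim, ["A"])
        expected = (0.9 + 0.2 + 0.3 + 0.25 + 0.35 + 0.8) / 6
        assert avg_self_similarity(cs, toy_sim) == pytest.approx(expected)

    def test_singletons_never_lower_than_coarser(self, toy_sim):
        # the all-singleton extreme dominates any coarser partition
        singletons = partition(toy_sim, ["A", "B", "C", "D"])
        for centers in (["A"], ["A", "C"], ["A", "B", "C"]):
            coarser = partition(toy_sim, centers)
            assert avg_self_similarity(singletons, toy_sim) >= avg_self_similarity(
                coarser, toy_sim
            )


class TestChooseClusterCount:
    def test_biggest_drop_rule(self):
        n, warned = pick_biggest_drop([0.45, 0.85, 0.80, 0.95])
        assert (n, warned) == (3, False)

    def test_strictly_increasing_warns_and_takes_least_increase(self):
        n, warned = pick_biggest_drop([0.1, 0.5, 0.55, 0.9])
        assert warned
        assert n == 3  # 0.5 -> 0.55 is the smallest increase

    def test_equal_drops_take_smaller_n(self):
        n, _ = pick_biggest_drop([0.9, 0.7, 0.8, 0.6])
        assert n == 2

    def test_uniform_matrix_warns(self):
        m = np.full((5, 5), 0.5)
        np.fill_diagonal(m, 1.0)
        sim = SimilarityMatrix(tuple("abcde"), m, DescriptorSet.ECFP4)
        with pytest.warns(UserWarning, match="avg-s never decreases"):
            curve = choose_cluster_count(sim, 5, "a")
        assert curve.warned_no_drop

    def test_curve_matches_fresh_partitions(self):
        rng = np.random.default_rng(5)
        sim = random_similarity_matrix(rng, 9)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = choose_cluster_count(sim, 9, sim.ids[2])
        centers = select_centers(sim, 9, sim.ids[2])
        for n in range(1, 10):
            cs = partition(sim, centers[:n])
            assert curve.avg_s[n - 1] == pytest.approx(
                avg_self_similarity(cs, sim), abs=1e-12
            )


class TestClusterCentre:
    def test_singleton(self, toy_sim):
        assert cluster_centre(["A"], toy_sim) == "A"

    def test_pair_tie_takes_first(self, toy_sim):
        assert cluster_centre(["A", "B"], toy_sim) == "A"

    def test_three_member_medoid(self, toy_sim):
        # mean sims: C=(0.8+0.2)/2=0.5, D=(0.8+0.3)/2=0.55, A=(0.2+0.3)/2=0.25
        assert cluster_centre(["C", "D", "A"], toy_sim) == "D"

    def test_empty_rejected(self, toy_sim):
        with pytest.raises(ValueError):
            cluster_centre([], toy_sim)


def make_cluster_set(assignment, centers):
    return ClusterSet(
        set_id=DescriptorSet.ECFP4, centers=centers, assignment=assignment
    )


class TestClusterSetSimilarity:
    def test_identical_partitions(self):
        p = make_cluster_set({"1": 0, "2": 0, "3": 1, "4": 1}, ("1", "3"))
        assert cluster_set_similarity(p, p) == 1.0

    def test_pair_disjoint_partitions(self):
        p1 = make_cluster_set({"1": 0, "2": 0, "3": 1, "4": 1}, ("1", "3"))
        p2 = make_cluster_set({"1": 0, "3": 0, "2": 1, "4": 1}, ("1", "2"))
        assert cluster_set_similarity(p1, p2) == 0.0

    def test_nested_partition_third(self):
        p1 = make_cluster_set({"1": 0, "2": 0, "3": 1}, ("1", "3"))
        p2 = make_cluster_set({"1": 0, "2": 0, "3": 0}, ("1",))
        assert cluster_set_similarity(p1, p2) == pytest.approx(1 / 3)

    def test_all_singletons_convention(self):
        p1 = make_cluster_set({"1": 0, "2": 1}, ("1", "2"))
        assert cluster_set_similarity(p1, p1) == 1.0

    def test_different_universes_rejected(self):
        p1 = make_cluster_set({"1": 0, "2": 0}, ("1",))
        p2 = make_cluster_set({"1": 0, "3": 0}, ("1",))
        with pytest.raises(ValueError):
            cluster_set_similarity(p1, p2)

    def test_symmetry_on_random_partitions(self):
        rng = np.random.default_rng(0)
        ids = [str(i) for i in range(12)]
        for _ in range(25):
            a1 = {i: int(rng.integers(4)) for i in ids}
            a2 = {i: int(rng.integers(4)) for i in ids}

            def normalize(a):
                used = sorted(set(a.values()))
                remap = {k: i for i, k in enumerate(used)}
                a = {cid: remap[k] for cid, k in a.items()}
                centers = []
                for k in range(len(used)):
                    centers.append(next(c for c, kk in a.items() if kk == k))
                return make_cluster_set(a, tuple(centers))

            p1, p2 = normalize(a1), normalize(a2)
            assert cluster_set_similarity(p1, p2) == pytest.approx(
                cluster_set_similarity(p2, p1)
            )


class TestBruteForceEquivalence:
    """The greedy selection/assignment must match a literal oracle."""

    @given(st.integers(0, 2**31 - 1), st.integers(2, 8))
    def test_matches_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        sim = random_similarity_matrix(rng, n)
        n_max = int(rng.integers(1, n + 1))
        seed_idx = int(rng.integers(n))
        expect_centers = brute_select(sim.values, n_max, seed_idx)
        got_centers = select_centers(sim, n_max, sim.ids[seed_idx])
        assert [sim.index(c) for c in got_centers] == expect_centers
        cs = partition(sim, got_centers)
        expect_assign = brute_assign(sim.values, expect_centers)
        assert {sim.index(c): k for c, k in cs.assignment.items()} == expect_assign
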