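"""Entropy, AMI (exact expected MI), V-measure, silhouette, stability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import (
    adjusted_mutual_info_score,
    homogeneity_completeness_v_measure,
)

import tinnibench as tb
from tinnibench import NO_DIAGNOSIS, KMeansConfig
from tinnibench.embed_cluster import ClusterAssignment, Embedding

from conftest import mc_expected_mi

partition_lists = st.lists(st.integers(0, 3), min_size=4, max_size=25)


class TestEntropy:
    def test_known_values(self):
        assert tb.entropy([0, 0, 0]) == 0.0
        assert tb.entropy([0, 1]) == pytest.approx(math.log(2), abs=1e-12)
        assert tb.entropy([0, 0, 1, 2]) == pytest.approx(1.0397, abs=1e-4)

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            tb.entropy([])


class TestAdjustedMutualInformation:
    def test_identical_nontrivial_partitions_score_one(self):
        u = [0, 0, 1, 1, 2]
        assert tb.adjusted_mutual_information(u, u) \
            == pytest.approx(1.0, abs=1e-12)

    def test_single_cluster_against_anything_scores_zero(self):
        assert tb.adjusted_mutual_information([0, 0, 0, 0], [0, 1, 2, 0]) == 0.0
        assert tb.adjusted_mutual_information([0, 0, 0], [0, 0, 0]) == 0.0

    def test_expected_mi_matches_permutation_oracle(self):
        """Exact hypergeometric E{MI} vs a 1e5-permutation Monte-Carlo
        estimate on the worked 4-sample example."""
        u = np.array([0, 0, 1, 1])
        v = np.array([0, 0, 1, 2])
        exact = tb.expected_mutual_information(u, v)
        mc, se = mc_expected_mi(u, v, n_perm=100_000, seed=0)
        assert abs(exact - mc) < 3 * se
        # and the AMI built from the MC estimate agrees with ours
        table = tb.ContingencyTable.from_labels(u, v)
        h_max = max(table.entropy_rows(), table.entropy_cols())
        ami_mc = (table.mutual_information() - mc) / (h_max - mc)
        assert tb.adjusted_mutual_information(u, v) \
            == pytest.approx(ami_mc, abs=10 * se)

    def test_matches_sklearn_max_normalisation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(6, 40)
            u = rng.integers(0, 4, size=n)
            v = rng.integers(0, 3, size=n)
            if len(set(u)) < 2 or len(set(v)) < 2:
                continue
            mine = tb.adjusted_mutual_information(u, v)
            ref = adjusted_mutual_info_score(u, v, average_method="max")
            assert mine == pytest.approx(ref, abs=1e-10)

    @settings(derandomize=True, max_examples=40)
    @given(partition_lists, partition_lists)
    def test_symmetry(self, u, v):
        m = min(len(u), len(v))
        u, v = np.array(u[:m]), np.array(v[:m])
        a = tb.adjusted_mutual_information(u, v)
        b = tb.adjusted_mutual_information(v, u)
        assert a == pytest.approx(b, abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(partition_lists, st.permutations([0, 1, 2, 3]))
    def test_invariance_to_cluster_relabeling(self, u, perm):
        v = np.array(u)[::-1]          # arbitrary second partition
        u = np.array(u)
        relabeled = np.array([perm[x] for x in u])
        a = tb.adjusted_mutual_information(u, v)
        b = tb.adjusted_mutual_information(relabeled, v)
        assert a == pytest.approx(b, abs=1e-12)

    def test_noise_samples_excluded_pairwise(self):
        u = np.array([0, 0, 1, 1, -1, 0])
        v = np.array([1, 1, 0, 0, 0, -1])
        expected = tb.adjusted_mutual_information(u[:4], v[:4])
        assert tb.adjusted_mutual_information(u, v) \
            == pytest.approx(expected, abs=1e-12)


class TestVMeasure:
    def test_identical_labelings_score_one(self):
        ref = np.array(["A", "A", "B", "B", "C"], object)
        pred = np.array([0, 0, 1, 1, 2])
        assert tb.v_measure(ref, pred).v == pytest.approx(1.0, abs=1e-12)

    def test_single_cluster_prediction_has_zero_homogeneity(self):
        ref = np.array(["A", "A", "B", "B"], object)
        res = tb.v_measure(ref, np.zeros(4, dtype=int))
        assert res.h == 0.0 and res.v == 0.0

    def test_singleton_prediction_worked_example(self):
        """ref (A,A,B,B) vs four singletons: h=1, c=0.5, v(0.1)=0.9167."""
        ref = np.array(["A", "A", "B", "B"], object)
        res = tb.v_measure(ref, np.arange(4), beta=0.1)
        assert res.h == pytest.approx(1.0, abs=1e-12)
        assert res.c == pytest.approx(0.5, abs=1e-12)
        assert res.v == pytest.approx(1.1 * 0.5 / 0.6, abs=1e-12)

    def test_unlabeled_and_noise_samples_excluded(self):
        ref = np.array(["A", "A", "B", "B", NO_DIAGNOSIS, "A"], object)
        pred = np.array([0, 0, 1, 1, 1, -1])
        res = tb.v_measure(ref, pred)
        assert res.n_evaluated == 4
        assert res.v == pytest.approx(1.0, abs=1e-12)

    def test_no_reference_labels_raises(self):
        ref = np.array([NO_DIAGNOSIS] * 4, object)
        with pytest.raises(ValueError, match="no reference labels"):
            tb.v_measure(ref, np.arange(4))

    def test_matches_sklearn_at_matching_beta(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            n = int(rng.integers(8, 40))
            ref = rng.choice(["A", "B", "C"], size=n).astype(object)
            pred = rng.integers(0, 4, size=n)
            mine = tb.v_measure(ref, pred, beta=0.1)
            h, c, v = homogeneity_completeness_v_measure(ref, pred, beta=0.1)
            assert mine.h == pytest.approx(h, abs=1e-10)
            assert mine.c == pytest.approx(c, abs=1e-10)
            assert mine.v == pytest.approx(v, abs=1e-10)

    def test_v_increases_with_homogeneity_at_fixed_completeness(self):
        beta = 0.1
        c = 0.6
        hs = np.linspace(0.05, 1.0, 25)
        vs = [(1 + beta) * h * c / (beta * h + c) for h in hs]
        assert all(b > a for a, b in zip(vs, vs[1:]))

    def test_log_base_invariance(self):
        """h, c, v are entropy ratios: recomputing every entropy in bits
        instead of nats leaves them unchanged."""
        ref = np.array(["A", "A", "B", "C", "B", "A", "C"], object)
        pred = np.array([0, 1, 1, 2, 2, 0, 2])
        res = tb.v_measure(ref, pred, beta=0.1)
        table = tb.ContingencyTable.from_labels(ref, pred)
        ln2 = math.log(2)
        counts = table.counts.astype(float)
        n = table.n

        def entropy_bits(c_vec):
            c_vec = c_vec[c_vec > 0]
            p = c_vec / c_vec.sum()
            return float(-(p * np.log2(p)).sum())

        h_c = entropy_bits(counts.sum(1))
        h_k = entropy_bits(counts.sum(0))
        h_ck = sum(
            counts[:, j].sum() / n * entropy_bits(counts[:, j])
            for j in range(counts.shape[1])
        )
        h_kc = sum(
            counts[i].sum() / n * entropy_bits(counts[i])
            for i in range(counts.shape[0])
        )
        assert res.h == pytest.approx(1 - h_ck / h_c, abs=1e-12)
        assert res.c == pytest.approx(1 - h_kc / h_k, abs=1e-12)


class TestSilhouette:
    def test_hand_computed_four_point_fixture(self):
        """{0, 0.1} vs {10, 10.1}: outer points have a=0.1, b=10.05;
        inner points a=0.1, b=9.95; the mean silhouette is 0.990."""
        coords = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        s = tb.silhouette_mean(coords, labels)
        hand = ((10.05 - 0.1) / 10.05 + (9.95 - 0.1) / 9.95) / 2
        assert s == pytest.approx(hand, abs=1e-10)
        assert s == pytest.approx(0.990, abs=1e-3)

    def test_identical_cluster_coordinates_score_zero(self):
        coords = np.zeros((6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert tb.silhouette_mean(coords, labels) == 0.0

    def test_bounded_in_minus_one_one(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            coords = rng.normal(size=(30, 2))
            labels = rng.integers(0, 3, size=30)
            s = tb.silhouette_mean(coords, labels)
            assert -1.0 <= s <= 1.0

    def test_noise_excluded_and_two_clusters_required(self):
        coords = np.array([[0.0], [0.1], [10.0], [10.1], [50.0]])
        labels = np.array([0, 0, 1, 1, -1])
        with_noise = tb.silhouette_mean(coords, labels)
        without = tb.silhouette_mean(coords[:4], labels[:4])
        assert with_noise == pytest.approx(without, abs=1e-12)
        with pytest.raises(ValueError):
            tb.silhouette_mean(coords, np.array([0, 0, 0, 0, -1]))


class TestStability:
    @staticmethod
    def gaussians(n, seed, centers=((0, 0), (12, 0), (0, 12))):
        rng = np.random.default_rng(seed)
        per = n // len(centers)
        return np.vstack([rng.normal(c, 1.0, (per, 2)) for c in centers])

    def test_identical_halves_are_perfectly_stable(self):
        X = self.gaussians(120, 0)
        emb = Embedding(X, "pca")
        res = tb.stability_inductive(emb, emb, KMeansConfig(k=3, seed=0))
        assert res.value == pytest.approx(1.0, abs=1e-12)
        assert res.kind == "ami_average" and len(res.components) == 2

    def test_well_separated_gaussians_are_stable(self):
        tr = Embedding(self.gaussians(300, 1), "pca")
        te = Embedding(self.gaussians(300, 2), "pca")
        res = tb.stability_inductive(tr, te, KMeansConfig(k=3, seed=0))
        assert res.value > 0.9

    def test_transductive_count_difference(self):
        a5 = ClusterAssignment(np.arange(5).repeat(3), 5)
        b5 = ClusterAssignment(np.arange(5).repeat(2), 5)
        b7 = ClusterAssignment(np.arange(7).repeat(2), 7)
        assert tb.stability_transductive(a5, b5).value == 0
        assert tb.stability_transductive(a5, b7).value == 2
        assert tb.stability_transductive(a5, a5).value == 0
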