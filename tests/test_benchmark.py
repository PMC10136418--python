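"""Grid sweep, eligibility, shortlist, profiling and repartition."""

import numpy as np
import pandas as pd
import pytest

import tinnibench as tb
from tinnibench import ColumnSchema, NO_DIAGNOSIS, PatientTable
from tinnibench.benchmark import (
    BenchmarkRecord,
    format_effect,
    pooled_cohens_d,
)
from tinnibench.embed_cluster import ClusterAssignment


@pytest.fixture(scope="module")
def small_sweep():
    """A full six-combination sweep on a small separable cohort."""
    spec = tb.make_separable_spec(
        n_patients=400, effect_low=2.0, effect_high=3.0, seed=1
    )
    table, _, _ = tb.generate_cohort(spec, seed=5)
    splits = tb.stratified_splits(table.labels.to_numpy(object), seed=5)
    grid = tb.GridSpec(
        pca_components=(2,),
        famd_components=(2,),
        tsne_components=(2,),
        tsne_perplexity=(20,),
        kmeans_k=(6,),
        dbscan_eps=(0.5, 1.0, 2.0, 3.0),
        dbscan_min_samples=(4,),
    )
    records = tb.run_benchmark(table, splits, grid, seed=5)
    return table, splits, records


def make_record(clusterer="kmeans", v=0.5, stability=0.8, sil=0.3, **kw):
    per = kw.pop("stability_per", [stability] * 3)
    rec = BenchmarkRecord(
        reduction_method=kw.pop("reduction", "pca"),
        reduction_params=kw.pop("reduction_params", {"n_components": 2}),
        clusterer_method=clusterer,
        clusterer_params=kw.pop("clusterer_params", {"k": 5}),
        v_per_partitioning=kw.pop("v_per", [v] * 3),
        stability_per_partitioning=per,
        silhouette_per_partitioning=[sil] * 3,
        n_clusters_per_half=[(5, 5)] * 3,
        assignments=[(np.arange(4), np.array([0, 0, 1, 1]))] * 3,
    )
    return rec


class TestGridSpec:
    def test_default_cardinality_matches_closed_form(self):
        grid = tb.GridSpec()
        n_reductions = 19 + 19 + 5 * 15       # pca + famd + tsne x perplexity
        n_clusterers = 19 + 100 * 14          # kmeans k + dbscan eps x min
        assert grid.n_grid_points() == n_reductions * n_clusterers

    def test_perplexity_grid_is_5_by_5_then_25_by_25(self):
        assert tb.benchmark.PERPLEXITY_GRID == (
            5, 10, 15, 20, 25, 30, 35, 40,
            50, 75, 100, 125, 150, 175, 200,
        )

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            tb.GridSpec(kmeans_k=())


class TestRunBenchmark:
    def test_all_six_method_combinations_present(self, small_sweep):
        _, _, records = small_sweep
        combos = {
            (r.reduction_method, r.clusterer_method)
            for r in records if r.status == "ok"
        }
        assert combos == {
            (red, cl)
            for red in ("pca", "famd", "tsne")
            for cl in ("kmeans", "dbscan")
        }

    def test_report_has_six_rows_and_three_metric_columns(self, small_sweep):
        _, _, records = small_sweep
        report = tb.benchmark_report(records)
        assert report.shape == (6, 3)
        assert list(report.columns) == ["v_measure", "stability", "silhouette"]

    def test_averages_equal_mean_of_stored_partitioning_values(self, small_sweep):
        _, _, records = small_sweep
        checked = 0
        for rec in records:
            if rec.status != "ok":
                continue
            assert rec.v_measure_avg == pytest.approx(
                np.mean(rec.v_per_partitioning)
            )
            assert rec.stability == pytest.approx(
                np.mean(rec.stability_per_partitioning)
            )
            assert len(rec.v_per_partitioning) == 3
            checked += 1
        assert checked >= 6

    def test_grid_record_count_matches_configuration(self, small_sweep):
        _, _, records = small_sweep
        # 3 reduction configs x (1 kmeans + 4 dbscan configs)
        assert len(records) == 3 * 5

    def test_out_of_range_dbscan_solutions_are_discarded(self, small_sweep):
        _, _, records = small_sweep
        flagged = [r for r in records if r.status == "out_of_range"]
        assert flagged, "fixture should produce some out-of-range solutions"
        lo, hi = 2, 20
        for rec in flagged:
            assert any(
                not (lo <= a <= hi and lo <= b <= hi)
                for a, b in rec.n_clusters_per_half
            )
            assert id(rec) not in [id(r) for r in tb.filter_eligible(records)]


class TestFilterEligible:
    def test_kmeans_ami_threshold_is_inclusive_at_0_7(self):
        below = make_record(stability=0.69)
        kept = make_record(stability=0.71)
        at = make_record(stability=0.70)
        out = tb.filter_eligible([below, kept, at])
        ids = [id(r) for r in out]
        assert id(below) not in ids and id(kept) in ids and id(at) in ids

    def test_dbscan_requires_zero_difference_on_every_partitioning(self):
        good = make_record("dbscan", stability_per=[0.0, 0.0, 0.0],
                           clusterer_params={"eps": 1.0, "min_samples": 3})
        bad = make_record("dbscan", stability_per=[0.0, 1.0, 0.0],
                          clusterer_params={"eps": 1.0, "min_samples": 3})
        out = tb.filter_eligible([good, bad])
        assert [id(r) for r in out] == [id(good)]

    def test_empty_input_gives_empty_output(self):
        assert tb.filter_eligible([]) == []


class TestShortlist:
    def test_top_n_by_v_measure_in_order(self):
        recs = [make_record(v=v) for v in (0.14, 0.38, 0.10, 0.35)]
        out = tb.shortlist(recs, n=3)
        assert [e.record.v_measure_avg for e in out] \
            == pytest.approx([0.38, 0.35, 0.14])

    def test_tie_broken_by_stability(self):
        weak = make_record(v=0.4, stability=0.75)
        strong = make_record(v=0.4, stability=0.9)
        out = tb.shortlist([weak, strong], n=1)
        assert out[0].record is strong

    def test_representative_comes_from_best_partitioning(self):
        rec = make_record()
        rec.v_per_partitioning = [0.2, 0.9, 0.4]
        out = tb.shortlist([rec], n=1)
        assert out[0].partitioning == 1

    def test_fewer_records_than_requested_warns(self):
        with pytest.warns(UserWarning, match="shortlist"):
            out = tb.shortlist([make_record()], n=3)
        assert len(out) == 1


class TestProfileClusters:
    @staticmethod
    def quant_table(values):
        frame = pd.DataFrame({"x": np.asarray(values, dtype=float)})
        return PatientTable(frame, {"x": ColumnSchema("quantitative")})

    def test_direct_formula_value(self):
        """mean_in 10, mean_out 8, pooled sd 2 -> D = 1.0, positive side."""
        rng = np.random.default_rng(0)
        inside = rng.normal(10, 2, 4000)
        outside = rng.normal(8, 2, 4000)
        d = pooled_cohens_d(inside, outside)
        assert d == pytest.approx(1.0, abs=0.08)
        table = self.quant_table(np.concatenate([inside, outside]))
        assign = ClusterAssignment(
            np.r_[np.zeros(4000, int), np.ones(4000, int)], 2
        )
        profiles = tb.profile_clusters(table, assign, d_threshold=0.3)
        assert profiles[0].positive[0][0] == "x"
        assert profiles[0].positive[0][1] == pytest.approx(d, abs=1e-12)
        assert profiles[1].negative[0][1] == pytest.approx(-d, abs=1e-12)

    def test_equal_means_listed_nowhere(self):
        table = self.quant_table([1, 2, 1, 2])
        assign = ClusterAssignment(np.array([0, 0, 1, 1]), 2)
        profiles = tb.profile_clusters(table, assign)
        assert profiles[0].positive == [] and profiles[0].negative == []

    def test_perfect_separator_reports_sentinel(self):
        """A binary feature that is all-yes inside and all-no outside has
        zero pooled variance: reported with the '>10' sentinel."""
        frame = pd.DataFrame({"g": ["yes"] * 3 + ["no"] * 5})
        table = PatientTable(
            frame, {"g": ColumnSchema("categorical", ("yes", "no"))}
        )
        assign = ClusterAssignment(np.r_[np.zeros(3, int), np.ones(5, int)], 2)
        profiles = tb.profile_clusters(table, assign)
        feats = dict(profiles[0].positive)
        assert np.isinf(feats["g=yes"])
        assert format_effect(feats["g=yes"]) == ">10"

    def test_lists_sorted_by_absolute_effect(self, small_sweep):
        table, _, records = small_sweep
        rec = next(r for r in records
                   if r.status == "ok" and r.clusterer_method == "kmeans")
        train, labels = rec.assignments[0]
        assign = ClusterAssignment(labels, int(labels.max()) + 1)
        profiles = tb.profile_clusters(table.subset(train), assign)
        for prof in profiles:
            mags = [abs(d) for _, d in prof.positive]
            assert mags == sorted(mags, reverse=True)
            assert all(d >= prof.threshold for _, d in prof.positive)
            assert all(d <= -prof.threshold for _, d in prof.negative)


class TestEndotypeRepartition:
    def test_uniform_null_expected_counts(self):
        """116 labeled patients spread over 20 clusters: expected 5.8 each."""
        rng = np.random.default_rng(1)
        labels = np.array(
            ["pulsatile"] * 116 + [NO_DIAGNOSIS] * 884, dtype=object
        )
        assign = ClusterAssignment(rng.integers(0, 20, size=1000), 20)
        rows = tb.endotype_repartition(assign, labels)
        assert len(rows) == 20
        assert all(r.expected == pytest.approx(5.8) for r in rows)
        assert sum(r.observed for r in rows) == 116

    def test_absent_endotype_has_no_rows(self):
        labels = np.array([NO_DIAGNOSIS] * 10, dtype=object)
        assign = ClusterAssignment(np.zeros(10, int), 1)
        assert tb.endotype_repartition(assign, labels) == []

    def test_observed_counts_conserve_endotype_totals(self, small_sweep):
        table, _, records = small_sweep
        rec = next(r for r in records
                   if r.status == "ok" and r.clusterer_method == "kmeans")
        train, labels = rec.assignments[0]
        half_labels = table.labels.to_numpy(object)[train]
        assign = ClusterAssignment(labels, int(labels.max()) + 1)
        rows = tb.endotype_repartition(assign, half_labels)
        for endo in {r.endotype for r in rows}:
            total = sum(r.observed for r in rows if r.endotype == endo)
            assert total == (half_labels == endo).sum()

    def test_size_weighted_null_sums_to_total(self):
        labels = np.array(["a"] * 30 + [NO_DIAGNOSIS] * 70, dtype=object)
        assign = ClusterAssignment(
            np.r_[np.zeros(80, int), np.ones(20, int)], 2
        )
        rows = tb.endotype_repartition(assign, labels,
                                       weight_by_cluster_size=True)
        assert sum(r.expected for r in rows) == pytest.approx(30.0)


class TestCountSeparatedEndotypes:
    def test_counts_majority_distinct_clusters_only(self):
        labels = np.array(
            ["a"] * 4 + ["b"] * 4 + ["c"] * 4 + [NO_DIAGNOSIS] * 4, object
        )
        # a -> cluster 0 (majority); b -> cluster 0 too (collision);
        # c -> cluster 2 (majority, alone)
        clusters = np.array([0, 0, 0, 1, 0, 0, 0, 1, 2, 2, 2, 1, 3, 3, 3, 3])
        assign = ClusterAssignment(clusters, 4)
        assert tb.count_separated_endotypes(assign, labels) == 1

    def test_no_majority_means_not_separated(self):
        labels = np.array(["a"] * 4 + [NO_DIAGNOSIS] * 2, object)
        clusters = np.array([0, 1, 2, 3, 0, 1])
        assert tb.count_separated_endotypes(
            ClusterAssignment(clusters, 4), labels
        ) == 0
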