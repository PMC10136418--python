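"""Grid-search benchmark, eligibility filtering, shortlisting and profiling.

For every combination of a dimensionality-reduction configuration and a
clusterer configuration, and for each of the three stratified 50-50
partitionings, the two halves are reduced independently (identical
hyperparameters and seed), the clusterer is fit and scored, and three
criteria are recorded: the V-measure (beta = 0.1) of the training-half
clustering against the partial endotype labels, the stability (averaged
four-clustering AMI for k-means; the cluster-count-difference proxy for
DBSCAN), and the mean silhouette.  Averages over the three partitionings
summarise each grid point.

Eligibility mirrors the protocol: k-means solutions need an averaged AMI
of at least 0.7; DBSCAN solutions need a cluster-count difference of 0 on
every partitioning and a cluster count inside the admissible range on both
halves.  The shortlist ranks eligible records by averaged V-measure and
hands back, per record, the representative clustering: the training-half
clustering of the partitioning achieving the record's best V-measure.

Selected clusterings are characterised by pooled Cohen's-D effect sizes of
every feature (categorical features expanded to binary level indicators)
between each cluster and the rest of the patients, and by the repartition
of diagnosed endotypes over clusters against a uniform-allocation null.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import NO_DIAGNOSIS, QUANTITATIVE, PatientTable
from .embed_cluster import (
    NOISE,
    ClusterAssignment,
    Embedding,
    KMeansConfig,
    fit_dbscan,
    fit_kmeans,
    predict_kmeans,
    reduce_famd,
    reduce_pca,
    reduce_tsne,
)
from .metrics import (
    adjusted_mutual_information,
    silhouette_mean,
    v_measure,
)
from .partitioning import SplitSet
from .preprocessing import encode

__all__ = [
    "GridSpec",
    "BenchmarkRecord",
    "ShortlistEntry",
    "ClusterProfile",
    "RepartitionRow",
    "run_benchmark",
    "filter_eligible",
    "shortlist",
    "profile_clusters",
    "endotype_repartition",
    "benchmark_report",
    "count_separated_endotypes",
]

#: t-SNE perplexity grid: 5 by 5 up to 40, then 25 by 25 from 50 to 200.
PERPLEXITY_GRID = tuple(range(5, 45, 5)) + tuple(range(50, 225, 25))


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid for the benchmark sweep."""

    pca_components: tuple[int, ...] = tuple(range(2, 21))
    famd_components: tuple[int, ...] = tuple(range(2, 21))
    tsne_components: tuple[int, ...] = tuple(range(2, 7))
    tsne_perplexity: tuple[float, ...] = PERPLEXITY_GRID
    kmeans_k: tuple[int, ...] = tuple(range(2, 21))
    dbscan_eps: tuple[float, ...] = tuple(
        round(0.1 * i, 1) for i in range(1, 101)
    )
    dbscan_min_samples: tuple[int, ...] = tuple(range(2, 16))
    dbscan_cluster_range: tuple[int, int] = (2, 20)
    reductions: tuple[str, ...] = ("pca", "famd", "tsne")
    clusterers: tuple[str, ...] = ("kmeans", "dbscan")

    def __post_init__(self) -> None:
        for name in (
            "pca_components", "famd_components", "tsne_components",
            "tsne_perplexity", "kmeans_k", "dbscan_eps", "dbscan_min_samples",
        ):
            if not getattr(self, name):
                raise ValueError(f"empty grid range {name!r}")

    def reduction_configs(self):
        if "pca" in self.reductions:
            for d in self.pca_components:
                yield "pca", {"n_components": d}
        if "famd" in self.reductions:
            for d in self.famd_components:
                yield "famd", {"n_components": d}
        if "tsne" in self.reductions:
            for d, px in itertools.product(
                self.tsne_components, self.tsne_perplexity
            ):
                yield "tsne", {"n_components": d, "perplexity": px}

    def clusterer_configs(self):
        if "kmeans" in self.clusterers:
            for k in self.kmeans_k:
                yield "kmeans", {"k": k}
        if "dbscan" in self.clusterers:
            for eps, ms in itertools.product(
                self.dbscan_eps, self.dbscan_min_samples
            ):
                yield "dbscan", {"eps": eps, "min_samples": ms}

    def n_grid_points(self) -> int:
        n_red = len(list(self.reduction_configs()))
        n_cl = len(list(self.clusterer_configs()))
        return n_red * n_cl


@dataclass
class BenchmarkRecord:
    """Averaged and per-partitioning scores of one grid point."""

    reduction_method: str
    reduction_params: dict
    clusterer_method: str
    clusterer_params: dict
    v_per_partitioning: list[float] = field(default_factory=list)
    stability_per_partitioning: list[float] = field(default_factory=list)
    silhouette_per_partitioning: list[float] = field(default_factory=list)
    n_clusters_per_half: list[tuple[int, int]] = field(default_factory=list)
    status: str = "ok"
    message: str = ""
    # Training-half clusterings retained for shortlisting/profiling:
    # one (train_indices, labels) pair per partitioning.
    assignments: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def v_measure_avg(self) -> float:
        return float(np.mean(self.v_per_partitioning))

    @property
    def stability(self) -> float:
        return float(np.mean(self.stability_per_partitioning))

    @property
    def silhouette_avg(self) -> float:
        return float(np.mean(self.silhouette_per_partitioning))

    @property
    def hyperparameter_tuple(self) -> tuple:
        red = tuple(sorted(self.reduction_params.items()))
        cl = tuple(sorted(self.clusterer_params.items()))
        return red + cl


def _embed_half(
    table: PatientTable, indices: np.ndarray, method: str, params: dict, seed: int
) -> Embedding:
    half = table.subset(indices)
    if method == "famd":
        return reduce_famd(half, params["n_components"])
    encoded = encode(half)
    if method == "pca":
        return reduce_pca(encoded, params["n_components"])
    if method == "tsne":
        return reduce_tsne(
            encoded, params["n_components"], params["perplexity"], seed
        )
    raise ValueError(f"unknown reduction method {method!r}")


def run_benchmark(
    table: PatientTable,
    splits: SplitSet,
    grid: GridSpec,
    seed: int = 0,
    beta: float = 0.1,
) -> list[BenchmarkRecord]:
    """Score every grid point over the three partitionings.

    ``table`` must be fully preprocessed (no missing cells).  Grid-point
    failures (e.g. DBSCAN collapsing to all noise) are recorded on the
    returned record with ``status='error'``, never fatal to the sweep.
    Embeddings are computed once per reduction configuration and half and
    shared across all clusterer configurations.
    """
    if table.labels is None:
        raise ValueError("the benchmark needs the partial label column")
    labels = table.labels.to_numpy(object)
    records: list[BenchmarkRecord] = []
    lo, hi = grid.dbscan_cluster_range

    for red_method, red_params in grid.reduction_configs():
        halves = [
            (
                _embed_half(table, train, red_method, red_params, seed),
                _embed_half(table, test, red_method, red_params, seed),
            )
            for train, test in splits.partitionings
        ]
        for cl_method, cl_params in grid.clusterer_configs():
            record = BenchmarkRecord(
                reduction_method=red_method,
                reduction_params=dict(red_params),
                clusterer_method=cl_method,
                clusterer_params=dict(cl_params),
            )
            try:
                for (train, test), (emb_tr, emb_te) in zip(
                    splits.partitionings, halves
                ):
                    if cl_method == "kmeans":
                        k = cl_params["k"]
                        model_tr, assign_tr = fit_kmeans(emb_tr, k, seed=seed)
                        model_te, assign_te = fit_kmeans(emb_te, k, seed=seed)
                        ami_tr = adjusted_mutual_information(
                            assign_tr, predict_kmeans(model_te, emb_tr)
                        )
                        ami_te = adjusted_mutual_information(
                            predict_kmeans(model_tr, emb_te), assign_te
                        )
                        stability = 0.5 * (ami_tr + ami_te)
                    else:
                        assign_tr = fit_dbscan(
                            emb_tr, cl_params["eps"], cl_params["min_samples"]
                        )
                        assign_te = fit_dbscan(
                            emb_te, cl_params["eps"], cl_params["min_samples"]
                        )
                        stability = float(
                            abs(assign_tr.n_clusters - assign_te.n_clusters)
                        )
                        if not (
                            lo <= assign_tr.n_clusters <= hi
                            and lo <= assign_te.n_clusters <= hi
                        ):
                            # solution outside the admissible cluster-count
                            # range: discarded, no further scoring
                            record.status = "out_of_range"
                            record.stability_per_partitioning.append(stability)
                            record.v_per_partitioning.append(np.nan)
                            record.silhouette_per_partitioning.append(np.nan)
                            record.n_clusters_per_half.append(
                                (assign_tr.n_clusters, assign_te.n_clusters)
                            )
                            record.assignments.append((train, assign_tr.labels))
                            continue
                    record.v_per_partitioning.append(
                        v_measure(labels[train], assign_tr.labels, beta=beta).v
                    )
                    record.stability_per_partitioning.append(stability)
                    record.silhouette_per_partitioning.append(
                        silhouette_mean(emb_tr, assign_tr)
                    )
                    record.n_clusters_per_half.append(
                        (assign_tr.n_clusters, assign_te.n_clusters)
                    )
                    record.assignments.append((train, assign_tr.labels))
            except Exception as exc:  # grid-point failure, not fatal
                record.status = "error"
                record.message = str(exc)
            records.append(record)
    return records


def filter_eligible(
    records: list[BenchmarkRecord],
    ami_min: float = 0.7,
    max_count_diff: int = 0,
) -> list[BenchmarkRecord]:
    """Keep stable solutions: AMI >= ami_min (k-means) or per-partitioning
    cluster-count difference <= max_count_diff (DBSCAN, in-range counts)."""
    keep = []
    for rec in records:
        if rec.status != "ok":
            continue
        if rec.clusterer_method == "kmeans":
            # tiny epsilon so the inclusive bound survives float averaging
            if rec.stability >= ami_min - 1e-12:
                keep.append(rec)
        else:
            if all(
                d <= max_count_diff for d in rec.stability_per_partitioning
            ):
                keep.append(rec)
    return keep


@dataclass
class ShortlistEntry:
    """One shortlisted record plus its representative clustering."""

    record: BenchmarkRecord
    partitioning: int
    train_indices: np.ndarray
    assignment: ClusterAssignment


def _stability_sort_key(rec: BenchmarkRecord) -> float:
    # Higher is better for AMI; for the DBSCAN proxy a smaller count
    # difference is better, so negate it onto the same ordering.
    if rec.clusterer_method == "kmeans":
        return rec.stability
    return -rec.stability


def shortlist(
    records: list[BenchmarkRecord], n: int = 3
) -> list[ShortlistEntry]:
    """Top-``n`` eligible records by averaged V-measure.

    Ties break by stability, then silhouette, then the smaller
    hyperparameter tuple.  Each entry carries the training-half clustering
    of the partitioning achieving the record's best V-measure.
    """
    if len(records) < n:
        warnings.warn(
            f"only {len(records)} eligible records for a shortlist of {n}"
        )
    ordered = sorted(
        records,
        key=lambda r: (
            -r.v_measure_avg,
            -_stability_sort_key(r),
            -r.silhouette_avg,
            r.hyperparameter_tuple,
        ),
    )
    entries = []
    for rec in ordered[:n]:
        best_p = int(np.argmax(rec.v_per_partitioning))
        train, labels = rec.assignments[best_p]
        n_clusters = int(np.unique(labels[labels != NOISE]).size)
        entries.append(
            ShortlistEntry(
                record=rec,
                partitioning=best_p,
                train_indices=train,
                assignment=ClusterAssignment(
                    labels=labels,
                    n_clusters=n_clusters,
                    source=f"{rec.clusterer_method} partitioning {best_p} (train half)",
                ),
            )
        )
    return entries


def benchmark_report(records: list[BenchmarkRecord]) -> pd.DataFrame:
    """Best performance per method combination (one row each).

    Rows are (reduction, clusterer) combinations; columns the three
    averaged criteria.  Within a combination the best record by averaged
    V-measure is reported, preferring eligible records when any exist.
    """
    rows = []
    records_ok = [r for r in records if r.status == "ok"]
    combos = sorted(
        {(r.reduction_method, r.clusterer_method) for r in records_ok}
    )
    for red, cl in combos:
        pool = [
            r for r in records_ok
            if r.reduction_method == red and r.clusterer_method == cl
        ]
        eligible = filter_eligible(pool)
        best = max(eligible or pool, key=lambda r: r.v_measure_avg)
        rows.append(
            {
                "reduction": red,
                "clusterer": cl,
                "v_measure": best.v_measure_avg,
                "stability": best.stability,
                "silhouette": best.silhouette_avg,
            }
        )
    return pd.DataFrame(rows).set_index(["reduction", "clusterer"])


# ---------------------------------------------------------------------------
# Cluster characterisation
# ---------------------------------------------------------------------------


@dataclass
class ClusterProfile:
    """Features differentiating one cluster from the rest of the patients."""

    cluster_id: int
    size: int
    positive: list[tuple[str, float]]
    negative: list[tuple[str, float]]
    threshold: float


def _indicator_frame(table: PatientTable) -> pd.DataFrame:
    """Numeric view for effect sizes: quantitative native, categorical one-hot."""
    cols = {}
    for name in table.data.columns:
        if table.schema[name].kind == QUANTITATIVE:
            cols[name] = table.data[name].to_numpy(dtype=float)
        else:
            values = table.data[name].to_numpy(object)
            for level in table.schema[name].levels:
                cols[f"{name}={level}"] = (values == level).astype(float)
    return pd.DataFrame(cols, index=table.data.index)


def pooled_cohens_d(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """Pooled Cohen's D of a cluster vs the rest.

    Zero pooled variance yields 0 when the means agree (constant feature)
    and +/-inf when they differ (perfectly separating feature; reported
    downstream as ">10").
    """
    n_in, n_out = len(x_in), len(x_out)
    if n_in < 1 or n_out < 1:
        return 0.0
    diff = float(x_in.mean() - x_out.mean())
    var_in = float(x_in.var(ddof=1)) if n_in > 1 else 0.0
    var_out = float(x_out.var(ddof=1)) if n_out > 1 else 0.0
    pooled = (
        (n_in - 1) * var_in + (n_out - 1) * var_out
    ) / max(n_in + n_out - 2, 1)
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        return math.copysign(math.inf, diff)
    return diff / math.sqrt(pooled)


def profile_clusters(
    table: PatientTable,
    assignment: ClusterAssignment,
    d_threshold: float = 0.3,
) -> list[ClusterProfile]:
    """Pooled Cohen's-D differentiation of every cluster vs the rest.

    Features with D >= d_threshold are listed as positive differentiation,
    D <= -d_threshold as negative, both sorted by |D| descending.
    """
    if len(assignment.labels) != table.n_patients:
        raise ValueError("assignment and table are not aligned")
    frame = _indicator_frame(table)
    X = frame.to_numpy(dtype=float)
    labels = assignment.labels
    profiles = []
    for cluster in range(assignment.n_clusters):
        inside = labels == cluster
        outside = (labels != cluster) & (labels != NOISE)
        effects = [
            (feat, pooled_cohens_d(X[inside, j], X[outside, j]))
            for j, feat in enumerate(frame.columns)
        ]
        positive = sorted(
            [(f, d) for f, d in effects if d >= d_threshold],
            key=lambda t: -abs(t[1]),
        )
        negative = sorted(
            [(f, d) for f, d in effects if d <= -d_threshold],
            key=lambda t: -abs(t[1]),
        )
        profiles.append(
            ClusterProfile(
                cluster_id=cluster,
                size=int(inside.sum()),
                positive=positive,
                negative=negative,
                threshold=d_threshold,
            )
        )
    return profiles


def format_effect(d: float) -> str:
    """Render an effect size; infinite (zero-variance) effects print as >10."""
    if math.isinf(d):
        return ">10" if d > 0 else "<-10"
    return f"{d:.2f}"


@dataclass
class RepartitionRow:
    """Observed vs expected-under-random endotype count in one cluster."""

    cluster_id: int
    endotype: str
    observed: int
    expected: float


def endotype_repartition(
    assignment: ClusterAssignment,
    labels,
    weight_by_cluster_size: bool = False,
) -> list[RepartitionRow]:
    """Cross-tabulate diagnosed endotypes against clusters.

    The expected count is the uniform-allocation null: the endotype's total
    in the clustered (non-noise) subset divided by the number of clusters.
    With ``weight_by_cluster_size`` the null allocates proportionally to
    cluster sizes instead.
    """
    labels = np.asarray(labels, dtype=object)
    clusters = assignment.labels
    if labels.shape != clusters.shape:
        raise ValueError("labels and assignment are not aligned")
    subset = clusters != NOISE
    k = assignment.n_clusters
    endotypes = sorted(
        {l for l in labels[subset] if l == l and l != NO_DIAGNOSIS}
    )
    cluster_sizes = np.array([(clusters == c).sum() for c in range(k)])
    subset_size = int(subset.sum())
    rows = []
    for endo in endotypes:
        members = subset & (labels == endo)
        total = int(members.sum())
        for c in range(k):
            observed = int((clusters[members] == c).sum())
            if weight_by_cluster_size and subset_size > 0:
                expected = total * cluster_sizes[c] / subset_size
            else:
                expected = total / k
            rows.append(
                RepartitionRow(
                    cluster_id=c, endotype=endo,
                    observed=observed, expected=float(expected),
                )
            )
    return rows


def count_separated_endotypes(assignment: ClusterAssignment, labels) -> int:
    """Number of endotypes isolated in their own majority cluster.

    An endotype counts as separated when a strict majority of its labeled
    members share one cluster and no other endotype's majority cluster is
    the same one.
    """
    labels = np.asarray(labels, dtype=object)
    clusters = assignment.labels
    majority_cluster: dict[str, int] = {}
    for endo in sorted(
        {l for l in labels if l == l and l != NO_DIAGNOSIS}
    ):
        member_clusters = clusters[(labels == endo) & (clusters != NOISE)]
        if member_clusters.size == 0:
            continue
        values, counts = np.unique(member_clusters, return_counts=True)
        top = counts.max()
        if top > member_clusters.size / 2:
            majority_cluster[endo] = int(values[np.argmax(counts)])
    used = list(majority_cluster.values())
    return sum(1 for c in used if used.count(c) == 1)
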