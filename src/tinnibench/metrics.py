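"""Evaluation criteria: AMI stability, V-measure on partial labels, silhouette.

Three quantities drive the benchmark:

* **Adjusted mutual information (AMI)** between two partitions U, V::

      AMI(U, V) = (MI(U, V) - E{MI}) / (max{H(U), H(V)} - E{MI})

  with E{MI} the expectation of MI under the permutation model with fixed
  marginals, computed by the exact closed-form hypergeometric sum.  AMI is
  1 for identical non-trivial partitions and ~0 at chance level.

* **V-measure** against the partial endotype diagnoses: the weighted
  harmonic mean ``(1 + beta) h c / (beta h + c)`` of homogeneity
  ``h = 1 - H(C|K)/H(C)`` and completeness ``c = 1 - H(K|C)/H(K)``.
  ``beta = 0.1`` weights homogeneity, rewarding clusterings whose clusters
  are diagnostically pure.  Only labeled samples enter the computation —
  in a cohort that is ~87% unlabeled, including the "no diagnosis" group
  as a class would swamp the signal.

* **Silhouette** ``(b - a)/max(a, b)`` averaged over samples, in the
  clustering (reduced) space.

Entropies are in nats throughout; every reported quantity is a ratio and
hence log-base invariant.  DBSCAN noise samples are excluded from the
silhouette and the V-measure, pairwise from the AMI, and from cluster
counts.

Stability is assessed per train/test half-pair: for an inductive clusterer
(k-means) both halves are fit, both models predict both halves, and the
AMI between the two same-half clusterings is averaged; for a transductive
clusterer (DBSCAN) the absolute difference of the two halves' cluster
counts serves as a proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.metrics import silhouette_score

from .data import NO_DIAGNOSIS
from .embed_cluster import (
    NOISE,
    ClusterAssignment,
    Embedding,
    KMeansConfig,
    fit_kmeans,
    predict_kmeans,
)

__all__ = [
    "ContingencyTable",
    "VMeasureResult",
    "StabilityResult",
    "entropy",
    "adjusted_mutual_information",
    "expected_mutual_information",
    "v_measure",
    "silhouette_mean",
    "stability_inductive",
    "stability_transductive",
]


def _as_labels(partition) -> np.ndarray:
    if isinstance(partition, ClusterAssignment):
        return partition.labels
    return np.asarray(partition)


@dataclass
class ContingencyTable:
    """Co-occurrence counts of two partitions, housing the MI quantities."""

    counts: np.ndarray
    n: int

    @classmethod
    def from_labels(cls, u, v) -> "ContingencyTable":
        u = _as_labels(u)
        v = _as_labels(v)
        if u.shape != v.shape:
            raise ValueError("partitions must cover the same samples")
        _, ui = np.unique(u, return_inverse=True)
        _, vi = np.unique(v, return_inverse=True)
        counts = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
        np.add.at(counts, (ui, vi), 1)
        return cls(counts=counts, n=int(counts.sum()))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def entropy_rows(self) -> float:
        return _entropy_from_counts(self.row_totals)

    def entropy_cols(self) -> float:
        return _entropy_from_counts(self.col_totals)

    def mutual_information(self) -> float:
        """MI(U, V) in nats from the contingency counts."""
        n = self.n
        nz = self.counts > 0
        nij = self.counts[nz].astype(float)
        outer = np.outer(self.row_totals, self.col_totals)[nz].astype(float)
        return float(np.sum((nij / n) * (np.log(n * nij) - np.log(outer))))

    def expected_mutual_information(self) -> float:
        """Exact E{MI} under the permutation null with fixed marginals.

        Closed-form sum over the feasible cell counts of each (i, j) pair,
        weighting each MI contribution by the hypergeometric probability
        of that cell count.
        """
        n = self.n
        a = self.row_totals.astype(np.int64)
        b = self.col_totals.astype(np.int64)
        lg = gammaln  # log-Gamma; log(x!) = gammaln(x + 1)
        log_n_fact = lg(n + 1)
        emi = 0.0
        for ai in a:
            for bj in b:
                lo = max(1, ai + bj - n)
                hi = min(ai, bj)
                if hi < lo:
                    continue
                nij = np.arange(lo, hi + 1, dtype=np.int64)
                term = (nij / n) * (np.log(n * nij / (ai * bj)))
                log_p = (
                    lg(ai + 1) + lg(bj + 1) + lg(n - ai + 1) + lg(n - bj + 1)
                    - log_n_fact - lg(nij + 1) - lg(ai - nij + 1)
                    - lg(bj - nij + 1) - lg(n - ai - bj + nij + 1)
                )
                emi += float(np.sum(term * np.exp(log_p)))
        return emi


def _entropy_from_counts(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    total = counts.sum()
    p = counts / total
    return float(-np.sum(p * np.log(p)))


def entropy(partition) -> float:
    """Shannon entropy (nats) of the partition's cluster-size proportions."""
    labels = _as_labels(partition)
    if labels.size < 1:
        raise ValueError("entropy requires at least one sample")
    _, counts = np.unique(labels, return_counts=True)
    return _entropy_from_counts(counts)


def expected_mutual_information(u, v) -> float:
    """Exact E{MI} of two partitions under the fixed-marginal permutation null."""
    return ContingencyTable.from_labels(u, v).expected_mutual_information()


def adjusted_mutual_information(u, v) -> float:
    """AMI with max-entropy normalisation and exact expected MI.

    Samples carrying the noise label in either partition are excluded
    pairwise.  Degenerate cases (both partitions trivial, or the
    denominator vanishing) return 0 by convention.
    """
    u = _as_labels(u)
    v = _as_labels(v)
    if u.shape != v.shape:
        raise ValueError("partitions must cover the same samples")
    keep = (u != NOISE) & (v != NOISE)
    u, v = u[keep], v[keep]
    if u.size == 0:
        raise ValueError("no samples left after noise exclusion")
    table = ContingencyTable.from_labels(u, v)
    h_u = table.entropy_rows()
    h_v = table.entropy_cols()
    h_max = max(h_u, h_v)
    if h_max == 0.0:  # both partitions put everything in one cluster
        return 0.0
    mi = table.mutual_information()
    emi = table.expected_mutual_information()
    denom = h_max - emi
    if abs(denom) < 1e-15:
        return 0.0
    return (mi - emi) / denom


@dataclass
class VMeasureResult:
    """Homogeneity, completeness and their weighted harmonic mean."""

    h: float
    c: float
    beta: float
    v: float
    n_evaluated: int


def v_measure(reference, predicted, beta: float = 0.1) -> VMeasureResult:
    """V-measure of a clustering against partial reference labels.

    Restricted to samples whose reference label is not the "no diagnosis"
    sentinel (and whose prediction is not noise).  ``h = 1`` when the
    reference entropy is 0, ``c = 1`` when the cluster entropy is 0.
    """
    reference = np.asarray(_as_labels(reference), dtype=object)
    predicted = _as_labels(predicted)
    if reference.shape != predicted.shape:
        raise ValueError("reference and prediction must cover the same samples")
    labeled = np.array(
        [r is not None and r == r and r != NO_DIAGNOSIS for r in reference]
    )
    keep = labeled & (np.asarray(predicted) != NOISE)
    if not keep.any():
        raise ValueError("no reference labels available for the V-measure")
    table = ContingencyTable.from_labels(reference[keep], predicted[keep])

    h_c = table.entropy_rows()   # H(C): reference classes
    h_k = table.entropy_cols()   # H(K): predicted clusters
    counts = table.counts.astype(float)
    n = table.n
    # H(C|K): entropy of classes within each cluster, cluster-weighted.
    h_c_given_k = 0.0
    for j in range(counts.shape[1]):
        col = counts[:, j]
        nj = col.sum()
        if nj > 0:
            h_c_given_k += (nj / n) * _entropy_from_counts(col)
    h_k_given_c = 0.0
    for i in range(counts.shape[0]):
        row = counts[i]
        ni = row.sum()
        if ni > 0:
            h_k_given_c += (ni / n) * _entropy_from_counts(row)

    h = 1.0 if h_c == 0.0 else 1.0 - h_c_given_k / h_c
    c = 1.0 if h_k == 0.0 else 1.0 - h_k_given_c / h_k
    denom = beta * h + c
    v = 0.0 if denom == 0.0 else (1.0 + beta) * h * c / denom
    return VMeasureResult(h=h, c=c, beta=beta, v=v, n_evaluated=int(keep.sum()))


def silhouette_mean(embedding, assignment) -> float:
    """Mean silhouette ``(b - a)/max(a, b)`` in the embedding space.

    Noise samples are excluded; at least two non-noise clusters are
    required.  Samples in singleton clusters score 0.
    """
    coords = (
        embedding.coordinates if isinstance(embedding, Embedding) else np.asarray(embedding)
    )
    labels = _as_labels(assignment)
    keep = labels != NOISE
    labels = labels[keep]
    coords = coords[keep]
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least two non-noise clusters")
    return float(silhouette_score(coords, labels, metric="euclidean"))


@dataclass
class StabilityResult:
    """Outcome of the stability protocol for one train/test half-pair."""

    kind: str  # "ami_average" | "cluster_count_diff"
    value: float
    components: tuple[float, float] | None = None


def stability_inductive(
    train_emb: Embedding, test_emb: Embedding, config: KMeansConfig
) -> StabilityResult:
    """Four-clustering AMI stability for an inductive clusterer (k-means).

    Fit the clusterer on each half, predict both models on both halves,
    and average the AMI between the two train-half clusterings and the AMI
    between the two test-half clusterings.
    """
    if train_emb.n_components != test_emb.n_components:
        raise ValueError("halves must share embedding dimensionality")
    model_tr, assign_tr = fit_kmeans(
        train_emb, config.k, seed=config.seed, n_init=config.n_init
    )
    model_te, assign_te = fit_kmeans(
        test_emb, config.k, seed=config.seed, n_init=config.n_init
    )
    on_train = (assign_tr, predict_kmeans(model_te, train_emb))
    on_test = (predict_kmeans(model_tr, test_emb), assign_te)
    ami_train = adjusted_mutual_information(*on_train)
    ami_test = adjusted_mutual_information(*on_test)
    return StabilityResult(
        kind="ami_average",
        value=0.5 * (ami_train + ami_test),
        components=(ami_train, ami_test),
    )


def stability_transductive(
    train_assign: ClusterAssignment, test_assign: ClusterAssignment
) -> StabilityResult:
    """Cluster-count-difference proxy for a transductive clusterer (DBSCAN)."""
    diff = abs(train_assign.n_clusters - test_assign.n_clusters)
    return StabilityResult(kind="cluster_count_diff", value=float(diff))
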