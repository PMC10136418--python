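"""Dimensionality reductions and clusterers with fit/predict contracts.

Three reducers — PCA, factor analysis of mixed data (FAMD), and t-SNE —
and two clusterers — k-means (squared Euclidean) and DBSCAN — wrapped so
that the four-clustering stability protocol can fit a model on one half of
a partitioning and apply it to the other.  All reducers are deterministic
under a fixed seed; t-SNE is seeded and PCA-initialised so that two halves
drawn from the same population produce comparable maps.

Cluster labels are canonical: non-noise clusters are relabeled to
consecutive integers by descending size (DBSCAN noise keeps the reserved
label -1), and nearest-centroid ties resolve to the lowest cluster index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN, KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .data import QUANTITATIVE, PatientTable
from .preprocessing import EncodedMatrix

__all__ = [
    "Embedding",
    "ClusterModel",
    "ClusterAssignment",
    "KMeansConfig",
    "reduce_pca",
    "reduce_famd",
    "reduce_tsne",
    "fit_kmeans",
    "predict_kmeans",
    "fit_dbscan",
]

NOISE = -1


@dataclass
class Embedding:
    """Reduced coordinates plus the method and hyperparameters that made them."""

    coordinates: np.ndarray
    method: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.isfinite(self.coordinates).all():
            raise ValueError("embedding coordinates must be finite")

    @property
    def n_samples(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ClusterModel:
    """A fitted k-means model: centroids in embedding space."""

    method: str
    centroids: np.ndarray
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if not np.isfinite(self.centroids).all():
            raise ValueError("centroids must be finite")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class ClusterAssignment:
    """Integer cluster labels per sample; -1 is the reserved noise label.

    ``n_clusters`` counts the clusters of the generating model; fitted
    clusterings use the canonical consecutive labels 0..n_clusters-1,
    while a prediction onto new samples may leave some clusters empty.
    """

    labels: np.ndarray
    n_clusters: int
    source: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        found = np.unique(self.labels[self.labels != NOISE])
        if found.size and (found.min() < 0 or found.max() >= self.n_clusters):
            raise ValueError("non-noise labels must lie in 0..n_clusters-1")


@dataclass(frozen=True)
class KMeansConfig:
    k: int
    seed: int = 0
    n_init: int = 10


def _canonicalize(raw_labels: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    """Relabel non-noise clusters by descending size (ties: original order).

    Returns (labels, n_clusters, order) where ``order`` maps new label ->
    original label.
    """
    raw_labels = np.asarray(raw_labels, dtype=int)
    uniq, counts = np.unique(raw_labels[raw_labels != NOISE], return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array(
        [remap[int(l)] if l != NOISE else NOISE for l in raw_labels], dtype=int
    )
    return labels, len(order), order


# ---------------------------------------------------------------------------
# Reductions
# ---------------------------------------------------------------------------

def reduce_pca(encoded: EncodedMatrix, n_components: int) -> Embedding:
    """Project onto the top-variance orthogonal axes of the encoded matrix."""
    X = encoded.values
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds the number of columns")
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(X)
    return Embedding(coords, "pca", {"n_components": n_components})


def famd_matrix(table: PatientTable) -> np.ndarray:
    """The weighted, centered FAMD input matrix of a fully imputed table.

    Quantitative columns are z-scored; each categorical level contributes
    an indicator column divided by the square root of its observed
    proportion; all columns are then centered.  PCA of this matrix is the
    FAMD decomposition, which balances the influence of quantitative and
    categorical blocks.
    """
    if table.missing_mask.to_numpy().any():
        raise ValueError("FAMD requires a fully imputed table")
    blocks = []
    for col in table.data.columns:
        if table.schema[col].kind == QUANTITATIVE:
            x = table.data[col].to_numpy(dtype=float)
            sd = x.std(ddof=0)
            if sd == 0:
                raise ValueError(f"degenerate constant column {col!r}")
            blocks.append((x - x.mean()) / sd)
        else:
            values = table.data[col].to_numpy(object)
            for level in table.schema[col].levels:
                ind = (values == level).astype(float)
                p = ind.mean()
                if p == 0.0:
                    continue  # unobserved level carries no information
                if p == 1.0:
                    raise ValueError(f"single-level categorical column {col!r}")
                blocks.append((ind - p) / np.sqrt(p))
    return np.column_stack(blocks)


def reduce_famd(table: PatientTable, n_components: int) -> Embedding:
    """Factor analysis of mixed data: PCA of the FAMD-weighted matrix."""
    M = famd_matrix(table)
    if n_components > M.shape[1]:
        raise ValueError("n_components exceeds the number of encoded columns")
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(M)
    return Embedding(coords, "famd", {"n_components": n_components})


def reduce_tsne(
    encoded: EncodedMatrix,
    n_components: int,
    perplexity: float,
    seed: int,
) -> Embedding:
    """Seeded t-SNE of the encoded matrix.

    Initialisation is the (deterministic) PCA projection so that two halves
    of the same cohort yield maps with comparable orientation — a
    prerequisite for cross-half centroid prediction in the stability
    protocol.  Identical inputs and seed give identical coordinates.
    """
    X = encoded.values
    n = X.shape[0]
    if n < 10:
        raise ValueError("t-SNE requires at least 10 samples")
    if perplexity >= n:
        raise ValueError("perplexity must be smaller than the sample count")
    method = "barnes_hut" if n_components <= 3 else "exact"
    model = TSNE(
        n_components=n_components,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        method=method,
        n_jobs=1,
    )
    coords = model.fit_transform(X)
    return Embedding(
        coords,
        "tsne",
        {"n_components": n_components, "perplexity": perplexity},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Clusterers
# ---------------------------------------------------------------------------

def fit_kmeans(
    embedding: Embedding, k: int, seed: int = 0, n_init: int = 10
) -> tuple[ClusterModel, ClusterAssignment]:
    """Best-inertia k-means over ``n_init`` seeded k-means++ starts."""
    X = embedding.coordinates
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of samples")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    labels, n_clusters, order = _canonicalize(km.labels_)
    centroids = km.cluster_centers_[order]
    model = ClusterModel("kmeans", centroids, k=k, seed=seed)
    # Re-assign with the canonical centroids so the tie rule (lowest index)
    # and the stored labels agree exactly.
    assignment = predict_kmeans(model, embedding)
    return model, assignment


def predict_kmeans(model: ClusterModel, embedding: Embedding) -> ClusterAssignment:
    """Nearest-centroid assignment (squared Euclidean, ties to lowest index)."""
    X = embedding.coordinates
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError("embedding dimensionality does not match centroids")
    d2 = cdist(X, model.centroids, metric="sqeuclidean")
    labels = np.argmin(d2, axis=1)  # argmin returns the first (lowest) index
    return ClusterAssignment(
        labels=labels,
        n_clusters=model.centroids.shape[0],
        source=f"kmeans(k={model.k})",
    )


def fit_dbscan(
    embedding: Embedding, eps: float, min_samples: int
) -> ClusterAssignment:
    """Density-reachability clustering; unreachable points get the noise label."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(
        embedding.coordinates
    )
    labels, n_clusters, _ = _canonicalize(raw)
    return ClusterAssignment(
        labels=labels,
        n_clusters=n_clusters,
        source=f"dbscan(eps={eps}, min_samples={min_samples})",
    )
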