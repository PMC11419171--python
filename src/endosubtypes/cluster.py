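"""Unsupervised sub-phenotype clustering and model selection.

Four algorithms are provided — spectral clustering on a k-nearest-neighbor
affinity graph, k-means, hierarchical agglomerative clustering and DBSCAN —
together with the three model-selection metrics used to pick among them:

* silhouette score under Manhattan distance (higher is better),
* distortion, the within-cluster sum of squared errors to centroids
  (elbow / local-minimum criterion),
* evenness, (largest cluster - smallest cluster) / n (lower is better).

``model_sweep`` evaluates each method over a K grid (2-20 by default) and
``select_model`` codifies the selection procedure: methods whose inferred
cluster count explodes past the grid are excluded, the remainder are
ranked by evenness, and the winning K is a strict interior local minimum
of the distortion curve, falling back to the silhouette maximum when no
method shows one.

Spectral clustering follows the normalized-Laplacian recipe: symmetrized
kNN connectivity affinity (Manhattan distance), top-K eigenvectors of
D^{-1/2} A D^{-1/2}, row normalization, then cluster assignment in
eigenspace by column-pivoted QR (each subject is assigned to the
representative row selected by the pivoting), with a seeded k-means
fallback when the QR assignment is degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
from scipy.cluster.hierarchy import fcluster, linkage as hclust_linkage
from scipy.cluster.vq import kmeans2
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .features import PhenotypeMatrix

__all__ = [
    "MethodParams",
    "ClusteringRun",
    "ClusterModel",
    "affinity_matrix",
    "spectral_cluster",
    "baseline_cluster",
    "silhouette_score",
    "distortion_score",
    "evenness_score",
    "model_sweep",
    "select_model",
]

METHODS = ("spectral", "kmeans", "hierarchical", "dbscan")


@dataclass(frozen=True)
class MethodParams:
    method: str = "spectral"
    K: int = 5
    affinity_neighbors: int = 10
    eps: float = 1.5
    min_samples: int = 5
    linkage: str = "average"
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass
class ClusteringRun:
    params: MethodParams
    labels: np.ndarray  # -1 marks DBSCAN noise
    n_clusters_found: int
    silhouette: float
    distortion: float
    evenness: float


@dataclass
class ClusterModel:
    """A fitted clustering kept for characterization and KNN transfer."""

    method: str
    K: int
    labels: np.ndarray
    training: PhenotypeMatrix
    embedding: np.ndarray | None = None  # spectral eigenvector coordinates


def _as_array(X) -> np.ndarray:
    if isinstance(X, PhenotypeMatrix):
        return np.asarray(X.values, dtype=float)
    return np.asarray(X, dtype=float)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..K-1 by order of first appearance (noise -1 kept)."""
    out = np.full(len(labels), -1, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# affinity graph
# ---------------------------------------------------------------------------

def affinity_matrix(X, affinity_neighbors: int = 10) -> np.ndarray:
    """Symmetrized kNN connectivity affinity under Manhattan distance.

    Edge (i, j) = 1 iff j is among i's ``affinity_neighbors`` nearest
    points or vice versa. Distance ties at the k-th neighbor are all
    included, so duplicated rows form a complete subgraph.
    """
    data = _as_array(X)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects for an affinity graph")
    k = min(affinity_neighbors, n - 1)
    D = cdist(data, data, metric="cityblock")
    np.fill_diagonal(D, np.inf)
    # k-th smallest distance per row; include all ties at that distance
    kth = np.partition(D, k - 1, axis=1)[:, k - 1]
    A = (D <= kth[:, None]).astype(float)
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0.0)
    return A


def _spectral_embedding(A: np.ndarray, K: int) -> np.ndarray:
    """Top-K eigenvectors of the normalized affinity D^{-1/2} A D^{-1/2}
    (equivalently the bottom of the symmetric normalized Laplacian)."""
    n = A.shape[0]
    d = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dm12 = np.where(d > 0, 1.0 / np.sqrt(d), 0.0)
    M = A * dm12[:, None] * dm12[None, :]
    if n <= 1500:
        # numpy's divide-and-conquer driver; LAPACK's default RRR driver
        # sporadically fails on graphs with many identical rows
        w, V = np.linalg.eigh(M)
        U = V[:, ::-1][:, :K]
    else:
        Ms = scipy.sparse.csr_matrix(M)
        w, V = scipy.sparse.linalg.eigsh(Ms, k=K, which="LA")
        U = V[:, np.argsort(w)[::-1]]
    return np.ascontiguousarray(U)


def _row_normalize(U: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(U, axis=1)
    norms[norms == 0] = 1.0
    return U / norms[:, None]


def _qr_assign(U: np.ndarray, K: int) -> np.ndarray | None:
    """Column-pivoted-QR cluster assignment in eigenspace.

    QR with pivoting on U^T picks K maximally independent rows of U as
    cluster representatives; every subject joins the representative with
    the largest absolute inner product. Returns None when degenerate
    (representatives nearly collinear or a cluster left empty)."""
    _, R, piv = scipy.linalg.qr(U.T, pivoting=True, mode="economic")
    C = U[piv[:K]]
    diag = np.abs(np.diag(R))
    if diag.min() < 1e-8 * max(diag.max(), 1.0):
        return None
    labels = np.abs(U @ C.T).argmax(axis=1)
    if len(np.unique(labels)) < K:
        return None
    return labels


def _seeded_kmeans(U: np.ndarray, K: int, seed: int, n_restarts: int = 10
                   ) -> tuple[np.ndarray, float]:
    """Best-of-restarts k-means (k-means++ init); ties go to the earliest
    restart."""
    rng = np.random.default_rng(seed)
    best_labels, best_sse = None, np.inf
    for _ in range(max(1, n_restarts)):
        s = int(rng.integers(2 ** 31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-cluster warnings
            _, labels = kmeans2(U, K, minit="++", seed=s)
        sse = distortion_score(U, labels)
        if sse < best_sse - 1e-12:
            best_sse, best_labels = sse, labels
    return best_labels, best_sse


def spectral_cluster(X, params: MethodParams, affinity: np.ndarray | None = None,
                     embedding: np.ndarray | None = None
                     ) -> tuple[ClusteringRun, np.ndarray]:
    """Normalized spectral clustering; returns the run and the K-column
    eigenvector embedding used for assignment."""
    data = _as_array(X)
    n, K = data.shape[0], params.K
    if K < 2:
        raise ValueError("spectral clustering needs K >= 2")
    if K > n:
        raise ValueError(f"K={K} exceeds n={n}")
    if affinity is None:
        affinity = affinity_matrix(data, params.affinity_neighbors)
    n_comp, _ = connected_components(scipy.sparse.csr_matrix(affinity), directed=False)
    if n_comp > K:
        warnings.warn(
            f"affinity graph has {n_comp} connected components > K={K}; "
            "labels returned but may merge components", stacklevel=2)
    if embedding is None:
        embedding = _spectral_embedding(affinity, K)
    U = _row_normalize(embedding[:, :K])
    labels = _qr_assign(U, K)
    if labels is None:
        labels, _ = _seeded_kmeans(U, K, params.seed, params.n_restarts)
    labels = _canonical_labels(labels)
    run = _make_run(data, labels, params)
    return run, embedding[:, :K]


# ---------------------------------------------------------------------------
# baseline methods
# ---------------------------------------------------------------------------

def _dbscan(data: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Plain density-reachability DBSCAN under Manhattan distance."""
    tree = cKDTree(data)
    neighborhoods = tree.query_ball_point(data, r=eps, p=1)
    n = data.shape[0]
    core = np.array([len(nb) >= min_samples for nb in neighborhoods])
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        # expand a new cluster from core point i
        labels[i] = cluster
        frontier = list(neighborhoods[i])
        while frontier:
            j = frontier.pop()
            if labels[j] == -1:
                labels[j] = cluster
                if core[j]:
                    frontier.extend(q for q in neighborhoods[j] if labels[q] == -1)
        cluster += 1
    return labels


def baseline_cluster(X, params: MethodParams) -> ClusteringRun:
    """k-means, hierarchical agglomerative, or DBSCAN."""
    data = _as_array(X)
    if params.method == "kmeans":
        labels, _ = _seeded_kmeans(data, params.K, params.seed, params.n_restarts)
    elif params.method == "hierarchical":
        metric = "euclidean" if params.linkage == "ward" else "cityblock"
        Z = hclust_linkage(data, method=params.linkage, metric=metric)
        labels = fcluster(Z, t=params.K, criterion="maxclust") - 1
    elif params.method == "dbscan":
        labels = _dbscan(data, params.eps, params.min_samples)
    else:
        raise ValueError(f"baseline_cluster does not handle {params.method!r}")
    labels = _canonical_labels(labels)
    return _make_run(data, labels, params)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def silhouette_score(X, labels, metric: str = "cityblock",
                     distances: np.ndarray | None = None) -> float:
    """Mean silhouette (b - a) / max(a, b) under the given metric
    (Manhattan by default). Noise points (label -1) are excluded;
    singleton-cluster members score 0. Raises on a single cluster."""
    data = _as_array(X)
    labels = np.asarray(labels)
    mask = labels != -1
    labels, data = labels[mask], data[mask]
    uniq, lab_idx = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    if distances is None:
        D = cdist(data, data, metric=metric)
    else:
        D = distances[np.ix_(mask, mask)]
    n, K = len(labels), len(uniq)
    onehot = np.zeros((n, K))
    onehot[np.arange(n), lab_idx] = 1.0
    sizes = onehot.sum(axis=0)
    sums = D @ onehot  # (n, K) total distance from i to each cluster
    own = sizes[lab_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[np.arange(n), lab_idx] / np.maximum(own - 1, 1)
        mean_other = sums / sizes[None, :]
        mean_other[np.arange(n), lab_idx] = np.inf
        b = mean_other.min(axis=1)
        s = (b - a) / np.maximum(a, b)
    s[own == 1] = 0.0  # singleton convention
    return float(np.mean(s))


def distortion_score(X, labels) -> float:
    """Within-cluster sum of squared Euclidean errors to centroids."""
    data = _as_array(X)
    labels = np.asarray(labels)
    sse = 0.0
    for lab in np.unique(labels):
        if lab == -1:
            continue
        pts = data[labels == lab]
        sse += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return sse


def evenness_score(labels) -> float:
    """(largest cluster - smallest cluster) / n over non-noise points;
    0 is perfectly even."""
    labels = np.asarray(labels)
    labels = labels[labels != -1]
    if len(labels) == 0:
        return float("nan")
    sizes = np.bincount(labels)
    sizes = sizes[sizes > 0]
    return float((sizes.max() - sizes.min()) / len(labels))


def _make_run(data: np.ndarray, labels: np.ndarray, params: MethodParams) -> ClusteringRun:
    non_noise = np.unique(labels[labels != -1])
    n_found = len(non_noise)
    try:
        sil = silhouette_score(data, labels)
    except ValueError:
        sil = float("nan")
    return ClusteringRun(
        params=params,
        labels=labels,
        n_clusters_found=n_found,
        silhouette=sil,
        distortion=distortion_score(data, labels) if n_found >= 1 else float("nan"),
        evenness=evenness_score(labels) if n_found >= 1 else float("nan"),
    )


# ---------------------------------------------------------------------------
# sweep + selection
# ---------------------------------------------------------------------------

def model_sweep(
    X,
    methods: Sequence[str] = METHODS,
    K_range: Iterable[int] = range(2, 21),
    seed: int = 0,
    base_params: MethodParams | None = None,
) -> pd.DataFrame:
    """Evaluate every (method, K) pair; DBSCAN contributes one row with
    its inferred cluster count. Returns a table with columns
    method, K, n_clusters_found, silhouette, distortion, evenness.

    The affinity graph, its eigenvectors and the pairwise-distance matrix
    are computed once and shared across the grid.
    """
    data = _as_array(X)
    K_list = sorted(set(int(k) for k in K_range))
    base = base_params or MethodParams()
    rows = []
    D_manhattan = cdist(data, data, metric="cityblock")
    affinity = embed = None
    for method in methods:
        if method == "dbscan":
            grid = [None]
        else:
            grid = K_list
        for K in grid:
            params = replace(base, method=method, K=K if K is not None else base.K,
                             seed=seed)
            try:
                if method == "spectral":
                    if affinity is None:
                        affinity = affinity_matrix(data, base.affinity_neighbors)
                    if embed is None:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            embed = _spectral_embedding(affinity, max(K_list))
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        run, _ = spectral_cluster(data, params, affinity=affinity,
                                                  embedding=embed[:, :K])
                else:
                    run = baseline_cluster(data, params)
                sil = run.silhouette
                if not np.isnan(sil) and run.n_clusters_found >= 2:
                    # recompute with the shared distance matrix (identical value,
                    # avoids an extra cdist); keeps dbscan noise handling
                    sil = silhouette_score(data, run.labels, distances=D_manhattan)
                rows.append((method, K if K is not None else run.n_clusters_found,
                             run.n_clusters_found, sil, run.distortion, run.evenness))
            except Exception as exc:  # record failure, keep sweeping
                warnings.warn(f"{method} K={K} failed: {exc}", stacklevel=2)
                rows.append((method, K, 0, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["method", "K", "n_clusters_found", "silhouette",
                       "distortion", "evenness"],
    )


def _strict_local_minima(K: np.ndarray, y: np.ndarray) -> list[int]:
    """K values at strict interior local minima of y over the sorted grid."""
    order = np.argsort(K)
    K, y = K[order], y[order]
    out = []
    for i in range(1, len(K) - 1):
        if np.isnan(y[i - 1]) or np.isnan(y[i]) or np.isnan(y[i + 1]):
            continue
        if y[i] < y[i - 1] and y[i] < y[i + 1]:
            out.append(int(K[i]))
    return out


@dataclass
class ModelSelection:
    method: str
    K: int
    rule: str  # "distortion_local_minimum" | "silhouette_maximum"
    justification: list[str] = field(default_factory=list)


def select_model(sweep: pd.DataFrame, max_clusters: int = 20) -> ModelSelection:
    """Codified model selection over a sweep table.

    1. Exclude methods whose inferred cluster count falls outside
       [2, max_clusters] on every row (e.g. DBSCAN inferring hundreds of
       clusters, or collapsing to all noise).
    2. Rank the survivors by mean evenness (ascending: balanced first).
    3. Walk that ranking and select the first method whose distortion
       curve has a strict interior local minimum; the selected K is the
       smallest such minimum. If no method shows one, fall back to the
       maximum-silhouette row among the survivors.
    """
    if sweep.empty:
        raise ValueError("empty sweep table")
    notes: list[str] = []
    surviving: list[str] = []
    for method, part in sweep.groupby("method", sort=False):
        ok = part["n_clusters_found"].between(2, max_clusters)
        if not ok.any():
            found = part["n_clusters_found"].tolist()
            notes.append(
                f"excluded {method}: inferred cluster counts {found} outside "
                f"[2, {max_clusters}]")
        else:
            surviving.append(method)
    if not surviving:
        raise ValueError("no method survives the exclusion rules: " + "; ".join(notes))

    mean_even = (
        sweep[sweep["method"].isin(surviving)]
        .groupby("method")["evenness"].mean().sort_values(kind="stable")
    )
    notes.append("evenness ranking (mean, ascending): "
                 + ", ".join(f"{m}={v:.3f}" for m, v in mean_even.items()))

    for method in mean_even.index:
        part = sweep[(sweep["method"] == method)
                     & sweep["n_clusters_found"].between(2, max_clusters)]
        if len(part) < 3:
            continue
        minima = _strict_local_minima(part["K"].to_numpy(float),
                                      part["distortion"].to_numpy(float))
        if minima:
            K_star = min(minima)
            notes.append(f"selected {method}: strict interior distortion local "
                         f"minimum at K={K_star} (all minima: {minima})")
            return ModelSelection(method, K_star, "distortion_local_minimum", notes)
        notes.append(f"{method}: no strict interior distortion local minimum")

    pool = sweep[sweep["method"].isin(surviving)].dropna(subset=["silhouette"])
    if pool.empty:
        raise ValueError("no usable rows for silhouette fallback: " + "; ".join(notes))
    best = pool.loc[pool["silhouette"].idxmax()]
    notes.append(f"fallback: maximum silhouette at {best['method']} K={int(best['K'])}")
    return ModelSelection(str(best["method"]), int(best["K"]), "silhouette_maximum", notes)
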