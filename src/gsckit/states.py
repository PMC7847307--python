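"""GSC state discovery: similarity-fusion affinity + spectral clustering.

Bulk ATAC profiles (samples x catalog regions, fold enrichment) are compared
by Pearson correlation of log2(signal + 1); the correlation distance feeds
the similarity-network-fusion scaled-exponential kernel, and states are the
normalized-Laplacian spectral clusters of the resulting affinity. With a
single data type the fusion step reduces to its affinity kernel (no
cross-modality diffusion). New samples mapped onto the reference catalog are
allocated to a state by average-linkage hierarchical clustering together
with the reference cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

__all__ = [
    "SimilarityMatrix",
    "ClusterLabels",
    "affinity_matrix",
    "spectral_clusters",
    "select_k",
    "assign_new_sample",
    "cluster_agreement",
]


@dataclass
class SimilarityMatrix:
    """Symmetric non-negative sample affinity with its kernel parameters."""

    W: np.ndarray
    K: int
    mu: float
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("W must be symmetric")
        if (W < 0).any():
            raise ValueError("W must be non-negative")
        self.W = W

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class ClusterLabels:
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.min() < 0 or labels.max() >= self.k:
            raise ValueError("labels must lie in 0..k-1")
        self.labels = labels


def _correlation_distance(logmat: np.ndarray, sample_ids=None) -> np.ndarray:
    sd = logmat.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        names = [sample_ids[i] for i in bad] if sample_ids else bad.tolist()
        raise ValueError(f"constant (zero-variance) sample rows: {names}")
    d = 1.0 - np.corrcoef(logmat)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def affinity_matrix(
    signal: np.ndarray,
    K: int = 20,
    mu: float = 0.5,
    sample_ids: list[str] | None = None,
) -> SimilarityMatrix:
    """Scaled-exponential kernel affinity from correlation distance.

    d(i,j) = 1 - Pearson r of log2(signal+1) rows. With m_i the mean distance
    of sample i to its K nearest neighbors (K capped at n-1), the local scale
    is eps(i,j) = (m_i + m_j + d(i,j)) / 3 and

        W(i,j) = exp(-d(i,j)^2 / (mu * eps(i,j))).
    """
    X = np.asarray(signal, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    d = _correlation_distance(np.log2(X + 1.0), sample_ids)
    n = d.shape[0]
    K = min(K, n - 1)
    # mean distance to K nearest neighbors, excluding self
    sorted_d = np.sort(d, axis=1)[:, 1 : K + 1]
    m = sorted_d.mean(axis=1)
    eps = (m[:, None] + m[None, :] + d) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.exp(-(d**2) / (mu * eps))
    W[eps == 0] = 1.0  # identical profiles with identical neighborhoods
    W = (W + W.T) / 2.0
    return SimilarityMatrix(W=W, K=K, mu=mu, sample_ids=sample_ids or [])


def spectral_clusters(W: SimilarityMatrix | np.ndarray, k: int, seed: int = 0) -> ClusterLabels:
    """Normalized-Laplacian spectral clustering (Ng-Jordan-Weiss).

    The k leading eigenvectors of D^{-1/2} W D^{-1/2} are row-normalized and
    partitioned by k-means (fixed seed, 50 restarts).
    """
    A = W.W if isinstance(W, SimilarityMatrix) else np.asarray(W, dtype=float)
    n = A.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n_samples, got k={k}, n={n}")
    n_comp, _ = connected_components((A > 1e-12).astype(int), directed=False)
    if n_comp > k:
        warnings.warn(
            f"affinity graph has {n_comp} components > k={k}; labels may be arbitrary",
            RuntimeWarning,
        )
    deg = A.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh((L + L.T) / 2.0)
    U = vecs[:, -k:]  # eigenvectors of the k largest eigenvalues
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = U / norms
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    return ClusterLabels(labels=km.fit_predict(U), k=k)


def _affinity_to_distance(A: np.ndarray) -> np.ndarray:
    d = 1.0 - A / A.max()
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, None)


def select_k(
    W: SimilarityMatrix | np.ndarray,
    kmin: int = 2,
    kmax: int = 12,
    seed: int = 0,
) -> tuple[int, dict]:
    """Choose k over a candidate range by mean silhouette of spectral labels.

    Silhouette uses the affinity converted to a distance (1 - W/max W).
    Returns (k, diagnostics) where diagnostics carries per-k silhouettes and
    the eigengap spectrum of the normalized affinity. Ties go to smallest k.
    """
    A = W.W if isinstance(W, SimilarityMatrix) else np.asarray(W, dtype=float)
    n = A.shape[0]
    kmax = min(kmax, n - 1)
    dist = _affinity_to_distance(A)
    sil: dict[int, float] = {}
    for k in range(kmin, kmax + 1):
        labels = spectral_clusters(A, k, seed=seed).labels
        if len(np.unique(labels)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(dist, labels, metric="precomputed"))
    ks = sorted(sil)
    best = ks[int(np.argmax([sil[k] for k in ks]))]
    deg = A.sum(axis=1)
    deg[deg == 0] = 1.0
    L = np.eye(n) - A / np.sqrt(np.outer(deg, deg))
    eigvals = np.sort(np.linalg.eigvalsh((L + L.T) / 2.0))
    return best, {"silhouette": sil, "laplacian_eigenvalues": eigvals, "eigengap": np.diff(eigvals)}


def assign_new_sample(
    signal_vector: np.ndarray,
    reference_signal: np.ndarray,
    reference_labels: list[str],
) -> tuple[str, bool]:
    """Allocate a catalog-mapped sample to a state by hierarchical clustering.

    Average-linkage clustering of reference + query on correlation distance
    of log2(signal+1); the query takes the majority reference label of the
    smallest merge cluster containing it and >= 1 reference sample. Returns
    (state, tie_flag); ties break by state name order.
    """
    ref = np.asarray(reference_signal, dtype=float)
    X = np.vstack([ref, np.asarray(signal_vector, dtype=float)[None, :]])
    d = _correlation_distance(np.log2(X + 1.0))
    Z = linkage(squareform(d, checks=False), method="average")
    n = X.shape[0]
    query = n - 1
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    for step, (a, b, _, _) in enumerate(Z):
        new = members[int(a)] | members[int(b)]
        members[n + step] = new
        if query in new and len(new) > 1:
            refs = sorted(new - {query})
            votes: dict[str, int] = {}
            for r in refs:
                votes[reference_labels[r]] = votes.get(reference_labels[r], 0) + 1
            top = max(votes.values())
            winners = sorted(s for s, v in votes.items() if v == top)
            return winners[0], len(winners) > 1
    raise RuntimeError("unreachable: query never merged")


def cluster_agreement(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings of the same samples."""
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must cover the same samples")
    return float(adjusted_rand_score(labels_a, labels_b))
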