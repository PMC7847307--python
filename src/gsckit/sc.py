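"""Single-cell accessibility signatures: embedding, modules, deviation scores.

Cells (fragment counts over catalog regions) are embedded by TF-IDF + LSI
and grouped into accessibility modules by k-means with an elbow rule. Cells
are scored against region-set signatures with chromVAR-style deviation
scores: the observed signature count of a cell is compared with the count
expected from its sequencing depth and the signature's share of total
accessibility, then standardized against background region sets matched on
GC content and mean accessibility. Positive calls (one-sided, BH-corrected)
assign cells to cellular states (NPC/OPC/AC/MES), stem status (19-TF promoter
or shared-GSC signature), and GSC states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .intervals import Signature

__all__ = [
    "CellMatrix",
    "DeviationScores",
    "CellClusters",
    "tfidf_lsi",
    "cluster_cells",
    "elbow_k",
    "deviation_scores",
    "classify_cells",
    "call_positive",
    "module_dominance",
    "signature_correlation",
    "overlap_test",
]


@dataclass
class CellMatrix:
    """Sparse cell x region fragment counts with region GC and cell depth."""

    counts: sp.csr_matrix
    region_gc: np.ndarray
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.region_gc = np.asarray(self.region_gc, dtype=float)
        if self.region_gc.shape[0] != self.counts.shape[1]:
            raise ValueError("region_gc length must equal number of regions")
        if np.any((self.region_gc < 0) | (self.region_gc > 1)):
            raise ValueError("GC fractions must lie in [0, 1]")
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(self.counts.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_regions(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_depth(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


@dataclass
class DeviationScores:
    """Raw and background-standardized deviations for one signature.

    raw = (observed - expected) / expected with expected proportional to cell
    depth; z standardizes raw against ``n_background`` GC/accessibility-
    matched background signatures; p is the one-sided (enrichment) normal
    tail, q its BH correction across cells. Cells with zero depth are
    invalid (scores NaN).
    """

    signature: str
    raw: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_background: int
    valid: np.ndarray


@dataclass
class CellClusters:
    module: np.ndarray  # per-cell module id
    n_modules: int
    wss: dict[int, float] = field(default_factory=dict)


def tfidf_lsi(counts, n_dims: int = 30, seed: int = 0) -> np.ndarray:
    """TF-IDF transform + truncated SVD (latent semantic indexing).

    Term frequency per cell, inverse document frequency per region,
    log1p-scaled; the first singular component tracks depth and is dropped,
    returning a cells x n_dims embedding.
    """
    X = sp.csr_matrix(counts, dtype=float)
    n_cells, n_regions = X.shape
    if n_dims + 1 >= min(n_cells, n_regions):
        raise ValueError("n_dims must be < min(n_cells, n_regions) - 1")
    depth = np.asarray(X.sum(axis=1)).ravel()
    depth[depth == 0] = 1.0
    tf = sp.diags(1.0 / depth) @ X
    n_cells_per_region = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = n_cells / (1.0 + n_cells_per_region)
    mat = tf @ sp.diags(idf)
    mat = mat.multiply(1e4)
    mat.data = np.log1p(mat.data)
    svd = TruncatedSVD(n_components=n_dims + 1, random_state=seed)
    emb = svd.fit_transform(mat)
    return emb[:, 1:]


def elbow_k(wss: dict[int, float], kmin: int | None = None, kmax: int | None = None) -> int:
    """Elbow of a within-cluster-sum-of-squares sequence.

    Returns the k maximizing the second difference of log(WSS) (the point
    where the relative improvement collapses); candidates need WSS at k-1
    and k+1. Ties go to the smallest k.
    """
    ks = sorted(wss)
    kmin = ks[1] if kmin is None else max(kmin, ks[1])
    kmax = ks[-2] if kmax is None else min(kmax, ks[-2])
    best, best_stat = None, -np.inf
    for k in range(kmin, kmax + 1):
        if k - 1 not in wss or k + 1 not in wss:
            continue
        logw = np.log(np.maximum([wss[k - 1], wss[k], wss[k + 1]], 1e-12))
        stat = logw[0] - 2 * logw[1] + logw[2]
        if stat > best_stat + 1e-12:
            best, best_stat = k, stat
    if best is None:
        raise ValueError("no candidate k with neighbors on both sides")
    return best


def cluster_cells(
    embedding: np.ndarray, kmin: int = 4, kmax: int = 12, seed: int = 0
) -> CellClusters:
    """Accessibility modules: k-means with elbow selection of module count.

    WSS is computed for kmin-1 .. kmax+1 and the module count is the elbow
    (see :func:`elbow_k`); ties go to the smallest k.
    """
    X = np.asarray(embedding, dtype=float)
    ks = list(range(max(1, kmin - 1), min(kmax + 1, X.shape[0] - 1) + 1))
    wss: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        wss[k] = float(km.inertia_)
        labels[k] = km.labels_
    try:
        best = elbow_k(wss, kmin=kmin, kmax=kmax)
    except ValueError:
        best = kmin
    return CellClusters(module=labels[best], n_modules=best, wss=wss)


def _signature_counts(counts: sp.csr_matrix, cols: np.ndarray) -> np.ndarray:
    return np.asarray(counts[:, cols].sum(axis=1)).ravel()


def deviation_scores(
    cells: CellMatrix,
    signature: Signature,
    n_background: int = 50,
    seed: int | None = None,
    n_neighbors: int = 50,
) -> DeviationScores:
    """chromVAR-style deviation z-scores of cells against one signature.

    expected(c) = depth(c) * (signature total / grand total); raw is the
    fractional deviation (obs - exp)/exp. Each background draw replaces
    every signature region by a uniformly sampled one of its ``n_neighbors``
    nearest neighbors in standardized (GC, mean accessibility) space and
    recomputes raw; z standardizes against the background mean and SD.
    """
    sig = np.fromiter(signature.regions, dtype=int)
    if sig.max(initial=-1) >= cells.n_regions or sig.min(initial=0) < 0:
        raise ValueError("signature regions outside catalog")
    rng = np.random.default_rng(seed)
    counts = cells.counts
    depth = cells.cell_depth.astype(float)
    valid = depth > 0
    grand = depth.sum()
    region_tot = np.asarray(counts.sum(axis=0)).ravel()

    def raw_dev(cols: np.ndarray) -> np.ndarray:
        obs = _signature_counts(counts, cols)
        frac = region_tot[cols].sum() / grand
        exp = depth * frac
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(exp > 0, (obs - exp) / exp, np.nan)

    raw = raw_dev(sig)

    # background regions matched on (GC, mean accessibility)
    feats = np.column_stack([cells.region_gc, region_tot / max(cells.n_cells, 1)])
    feats = (feats - feats.mean(axis=0)) / np.where(feats.std(axis=0) == 0, 1, feats.std(axis=0))
    k = min(n_neighbors + 1, cells.n_regions)
    nn = NearestNeighbors(n_neighbors=k).fit(feats)
    neigh = nn.kneighbors(feats[sig], return_distance=False)
    neigh = np.array([row[row != s][: k - 1] for row, s in zip(neigh, sig)])

    bg = np.empty((n_background, cells.n_cells))
    for b in range(n_background):
        picks = neigh[np.arange(len(sig)), rng.integers(0, neigh.shape[1], size=len(sig))]
        bg[b] = raw_dev(picks)
    mu = bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=1)
    sd[sd == 0] = np.nan
    z = (raw - mu) / sd
    p = stats.norm.sf(z)
    q = np.full_like(p, np.nan)
    ok = valid & np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    raw = np.where(valid, raw, np.nan)
    z = np.where(valid, z, np.nan)
    return DeviationScores(
        signature=signature.name, raw=raw, z=z, p=p, q=q,
        n_background=n_background, valid=valid,
    )


def call_positive(dev: DeviationScores, alpha: float = 0.05) -> np.ndarray:
    """Boolean per-cell enrichment call at BH-adjusted q <= alpha."""
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(dev.q), False, dev.q <= alpha)


def classify_cells(
    devs: dict[str, DeviationScores], alpha: float = 0.05
) -> list[set[str]]:
    """Per-cell set of cellular states with significant enrichment."""
    states = sorted(devs)
    n_cells = len(devs[states[0]].q)
    calls = {s: call_positive(devs[s], alpha) for s in states}
    return [{s for s in states if calls[s][c]} for c in range(n_cells)]


def module_dominance(
    clusters: CellClusters, calls: list[set[str]], fold: float = 2.0
) -> dict[int, tuple[str, tuple[str, ...]]]:
    """Dominant cellular state(s) per accessibility module at a fold cut-off.

    A single state dominates a module iff its cell count is >= fold x every
    other state's count; otherwise the top two states dominate as a pair iff
    their combined count is >= fold x every remaining state's count and each
    of the two exceeds every remaining count; otherwise the module is mixed.
    """
    out: dict[int, tuple[str, tuple[str, ...]]] = {}
    states = sorted({s for cs in calls for s in cs})
    for m in range(clusters.n_modules):
        idx = np.flatnonzero(clusters.module == m)
        counts = {s: sum(1 for c in idx if s in calls[c]) for s in states}
        ranked = sorted(counts, key=lambda s: (-counts[s], s))
        if not idx.size or not states or counts[ranked[0]] == 0:
            out[m] = ("mixed", ())
            continue
        top = ranked[0]
        if all(counts[top] >= fold * counts[s] for s in states if s != top):
            out[m] = ("single", (top,))
            continue
        if len(ranked) >= 2:
            pair = ranked[:2]
            rest = ranked[2:]
            combined = counts[pair[0]] + counts[pair[1]]
            if all(combined >= fold * counts[s] for s in rest) and all(
                counts[p] > counts[s] for p in pair for s in rest
            ):
                out[m] = ("pair", tuple(sorted(pair)))
                continue
        out[m] = ("mixed", ())
    return out


def signature_correlation(z_a: np.ndarray, z_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of two per-cell z-score vectors with t-test p."""
    a = np.asarray(z_a, dtype=float)
    b = np.asarray(z_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need >= 3 cells with finite scores")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def overlap_test(set_a, set_b, universe_size: int) -> float:
    """Upper-tail hypergeometric p of the overlap of two sets.

    P(X >= |a & b|) with X ~ Hypergeom(universe_size, |a|, |b|).
    """
    a, b = set(set_a), set(set_b)
    n_a, n_b = len(a), len(b)
    if n_a > universe_size or n_b > universe_size:
        raise ValueError("set sizes exceed universe")
    overlap = len(a & b)
    if overlap > min(n_a, n_b):  # pragma: no cover - impossible with true sets
        raise ValueError("overlap exceeds smaller set")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, n_a, n_b))
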