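"""Genomic intervals, peak catalogs and region-set definitions.

Coordinates are 0-based half-open (BED convention). A *peak catalog* is the
union of per-sample MACS2-style peak calls with overlapping intervals merged
(>= 1 bp overlap); each sample's q-values and fold-enrichment signal are then
mapped onto the merged regions. Region sets derived from the catalog:

* state-exclusive regions -- called at a strict q in >= 1 sample of one state
  and not called at a lenient q in any sample of the other states;
* shared regions -- occupied by at least ``min_samples`` samples (the
  "majority of GSCs" signature uses > 14 of 27);
* differential state peaks -- rank-sum test per region, BH correction, plus a
  fold-change filter on mean signal;
* promoter windows around annotated TSSs, strand-aware.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Interval",
    "PeakCall",
    "SamplePeaks",
    "PeakCatalog",
    "GeneAnnotation",
    "Signature",
    "build_catalog",
    "exclusive_regions",
    "shared_regions",
    "differential_state_peaks",
    "promoter_regions",
    "map_sample_to_catalog",
    "merge_intervals",
    "overlapping_region_indices",
    "promoter_signature",
]


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeakCall:
    """A called peak with its FDR-adjusted significance and fold enrichment."""

    interval: Interval
    q: float
    signal: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must be in [0, 1], got {self.q}")
        if self.signal < 0:
            raise ValueError("signal (fold enrichment) must be >= 0")


@dataclass
class SamplePeaks:
    """Peak calls of one sample, optionally labeled with its GSC state."""

    sample_id: str
    calls: list[PeakCall]
    state: str | None = None


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class Signature:
    """A named set of catalog region indices."""

    name: str
    regions: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.regions) == 0:
            raise ValueError(f"signature {self.name!r} is empty")
        self.regions = frozenset(int(i) for i in self.regions)


@dataclass
class PeakCatalog:
    """Merged union of peak calls with per-sample q and signal matrices.

    ``qmat[i, j]`` is sample i's best (minimum) q-value over region j, 1.0
    where the sample has no call; ``signal[i, j]`` is the maximum fold
    enrichment, 0.0 where absent.
    """

    regions: list[Interval]
    sample_ids: list[str]
    qmat: np.ndarray
    signal: np.ndarray
    states: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_s, n_r = len(self.sample_ids), len(self.regions)
        if self.qmat.shape != (n_s, n_r) or self.signal.shape != (n_s, n_r):
            raise ValueError("matrix shapes do not match samples x regions")
        if not self.states:
            self.states = [None] * n_s

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def occupancy(self, q: float = 0.05) -> np.ndarray:
        """Boolean sample x region matrix of calls at q-value threshold ``q``."""
        return self.qmat <= q


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Merge intervals overlapping by >= 1 bp; result sorted, disjoint."""
    merged: list[Interval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(Interval(iv.chrom, iv.start, iv.end))
    return merged


def _region_index(regions: list[Interval]):
    """Per-chromosome sorted (starts, ends, index) arrays for overlap lookup."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    order = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "idx": np.arange(len(regions)),
        }
    )
    for chrom, grp in order.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        by_chrom[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["idx"].to_numpy(),
        )
    return by_chrom


def _overlap_hits(index, iv: Interval) -> np.ndarray:
    """Indices of (sorted, disjoint) catalog regions overlapping ``iv``."""
    if iv.chrom not in index:
        return np.array([], dtype=int)
    starts, ends, idx = index[iv.chrom]
    lo = np.searchsorted(ends, iv.start, side="right")
    hi = np.searchsorted(starts, iv.end, side="left")
    return idx[lo:hi]


def build_catalog(samples: list[SamplePeaks]) -> PeakCatalog:
    """Union of all samples' peaks, merged, with q/signal mapped per sample.

    Where several calls of one sample overlap the same merged region, the
    minimum q and the maximum signal are kept.
    """
    if not samples:
        raise ValueError("build_catalog requires at least one sample")
    all_ivs = [c.interval for s in samples for c in s.calls]
    if not all_ivs:
        raise ValueError("no peak calls in any sample")
    regions = merge_intervals(all_ivs)
    index = _region_index(regions)
    n_s, n_r = len(samples), len(regions)
    qmat = np.ones((n_s, n_r))
    signal = np.zeros((n_s, n_r))
    for i, s in enumerate(samples):
        for call in s.calls:
            for j in _overlap_hits(index, call.interval):
                qmat[i, j] = min(qmat[i, j], call.q)
                signal[i, j] = max(signal[i, j], call.signal)
    return PeakCatalog(
        regions=regions,
        sample_ids=[s.sample_id for s in samples],
        qmat=qmat,
        signal=signal,
        states=[s.state for s in samples],
    )


def _resolve_labels(catalog: PeakCatalog, state_labels=None) -> np.ndarray:
    if state_labels is None:
        state_labels = catalog.states
    if isinstance(state_labels, dict):
        state_labels = [state_labels.get(s) for s in catalog.sample_ids]
    labels = np.asarray(state_labels, dtype=object)
    if len(labels) != catalog.n_samples:
        raise ValueError("one state label per sample required")
    missing = [s for s, l in zip(catalog.sample_ids, labels) if l is None]
    if missing:
        raise ValueError(f"unlabeled samples: {missing}")
    return labels


def exclusive_regions(
    catalog: PeakCatalog,
    state_labels=None,
    q_strict: float = 0.05,
    q_lenient: float = 0.2,
) -> dict[str, set[int]]:
    """State-exclusive catalog regions.

    A region is exclusive to state S iff it is called at q <= ``q_strict`` in
    at least one sample of S and is not called at q <= ``q_lenient`` in any
    sample outside S. Exclusive sets are pairwise disjoint by construction;
    this is asserted on every run.
    """
    if q_strict > q_lenient:
        raise ValueError("q_strict must be <= q_lenient")
    labels = _resolve_labels(catalog, state_labels)
    strict = catalog.qmat <= q_strict
    lenient = catalog.qmat <= q_lenient
    out: dict[str, set[int]] = {}
    for state in sorted({str(l) for l in labels}):
        in_state = labels == state
        called_in = strict[in_state].any(axis=0)
        absent_out = ~lenient[~in_state].any(axis=0)
        out[state] = set(np.flatnonzero(called_in & absent_out).tolist())
    sets = list(out.values())
    for a in range(len(sets)):
        for b in range(a + 1, len(sets)):
            assert not (sets[a] & sets[b]), "exclusive sets must be disjoint"
    return out


def shared_regions(
    catalog: PeakCatalog, q: float = 0.05, min_samples: int = 15
) -> set[int]:
    """Regions occupied (at q) by >= ``min_samples`` samples.

    The shared-GSC stem signature uses regions accessible in a majority of
    the 27 GSC lines (> 14 of 27, i.e. >= 15).
    """
    if min_samples > catalog.n_samples:
        raise ValueError("min_samples exceeds number of samples")
    counts = catalog.occupancy(q).sum(axis=0)
    return set(np.flatnonzero(counts >= min_samples).tolist())


def differential_state_peaks(
    catalog: PeakCatalog,
    state_labels=None,
    fc: float = 2.0,
    q: float = 0.05,
) -> dict[str, set[int]]:
    """Per-state differentially accessible regions (state vs all others).

    Rank-sum (Wilcoxon/Mann-Whitney) test on fold-enrichment signal per
    region, BH correction across regions, keep regions with ratio of mean
    signal > ``fc`` and adjusted q <= ``q``.
    """
    labels = _resolve_labels(catalog, state_labels)
    out: dict[str, set[int]] = {}
    for state in sorted({str(l) for l in labels}):
        in_state = labels == state
        if in_state.sum() < 2 or (~in_state).sum() < 2:
            raise ValueError(f"state {state!r} needs >= 2 samples on each side")
        a = catalog.signal[in_state]
        b = catalog.signal[~in_state]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant regions -> exact-tie warnings
            res = stats.mannwhitneyu(a, b, axis=0, method="asymptotic")
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        mean_a = a.mean(axis=0)
        mean_b = b.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(mean_b > 0, mean_a / mean_b, np.where(mean_a > 0, np.inf, 0.0))
        keep = (ratio > fc) & (qvals <= q)
        out[state] = set(np.flatnonzero(keep).tolist())
    return out


def promoter_regions(
    annotation: list[GeneAnnotation],
    upstream: int = 2000,
    downstream: int = 500,
) -> dict[str, Interval]:
    """Strand-aware promoter windows around each TSS.

    [tss - upstream, tss + downstream) on '+', mirrored on '-'; negative
    coordinates are clipped at 0.
    """
    out: dict[str, Interval] = {}
    for g in annotation:
        if g.strand == "+":
            start, end = g.tss - upstream, g.tss + downstream
        else:
            start, end = g.tss - downstream, g.tss + upstream
        out[g.gene_id] = Interval(g.chrom, max(0, start), max(1, end))
    return out


def map_sample_to_catalog(sample: SamplePeaks, catalog: PeakCatalog) -> np.ndarray:
    """Map a new sample's fold-enrichment signal onto catalog regions.

    Per region: max signal over overlapping calls, 0 where no call overlaps.
    """
    index = _region_index(catalog.regions)
    vec = np.zeros(catalog.n_regions)
    for call in sample.calls:
        for j in _overlap_hits(index, call.interval):
            vec[j] = max(vec[j], call.signal)
    return vec


def overlapping_region_indices(
    catalog: PeakCatalog, intervals: list[Interval]
) -> set[int]:
    """Catalog region indices overlapping (>= 1 bp) any of ``intervals``."""
    index = _region_index(catalog.regions)
    hits: set[int] = set()
    for iv in intervals:
        hits.update(_overlap_hits(index, iv).tolist())
    return hits


def promoter_signature(
    name: str,
    catalog: PeakCatalog,
    annotation: list[GeneAnnotation],
    genes: list[str] | None = None,
    upstream: int = 2000,
    downstream: int = 500,
) -> Signature:
    """Signature of catalog regions overlapping the promoters of ``genes``."""
    proms = promoter_regions(annotation, upstream, downstream)
    if genes is not None:
        missing = sorted(set(genes) - set(proms))
        if missing:
            raise KeyError(f"genes missing from annotation: {missing}")
        proms = {g: proms[g] for g in genes}
    return Signature(name, frozenset(overlapping_region_indices(catalog, list(proms.values()))))
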