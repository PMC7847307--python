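"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the shape of the study's inputs at desk scale: a
27-sample bulk ATAC cohort with three planted GSC states (13 Reactive, 9
Constructive, 5 Invasive) and state-exclusive region blocks; a ~1,000-cell
fragment-count matrix with four planted cellular states and a minority stem
population; a reference FPKM expression matrix with planted state
centroids; a tumor cohort whose expression mixes the state centroids with a
continuous Invasive weight that also scales its hazard; exponential
survival with group hazard ratios; and Bernoulli motif-hit matrices with
planted enrichment. All generators are pure functions of (config, seed).

Design notes baked into the defaults: counts are multinomial given a drawn
per-cell depth, so depths are conserved exactly; q-values of truly present
peaks are drawn below the strict 0.05 filter and weak spurious calls above
0.25, so the lenient 0.2 filter is unambiguous; region GC is uniform on
[0.3, 0.7] and independent of state unless the ``gc_bias`` switch couples
GC with accessibility to stress background matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .intervals import Interval, PeakCall, SamplePeaks
from .sc import CellMatrix
from .survival import SurvivalRecord

__all__ = [
    "SimConfig",
    "Truth",
    "simulate_bulk_peaks",
    "simulate_cell_matrix",
    "simulate_expression",
    "simulate_tumor_cohort",
    "simulate_survival",
    "simulate_motif_hits",
]

CELL_STATES = ("AC", "MES", "NPC", "OPC")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all synthetic generators.

    The bulk cohort mirrors the study: 27 GSC lines split 13/9/5 across the
    Reactive/Constructive/Invasive states, with a fraction of latent catalog
    regions exclusively accessible per state. Hazard ratios default to the
    xenograft estimates (Constructive 1.3, Invasive 3.5 vs Reactive).
    """

    # bulk peak cohort
    samples_per_state: dict[str, int] = field(
        default_factory=lambda: {"Reactive": 13, "Constructive": 9, "Invasive": 5}
    )
    catalog_size: int = 1000
    exclusive_frac: float = 0.1  # per state
    shared_frac: float = 0.2
    presence_prob: float = 0.6  # background regions per sample
    q_present: tuple[float, float] = (1e-6, 0.04)
    q_absent: tuple[float, float] = (0.25, 1.0)
    weak_call_prob: float = 0.2
    region_width: int = 300
    region_spacing: int = 1000
    jitter: int = 50
    signal_logmean: float = np.log(4.0)
    signal_logsd: float = 0.5

    # single-cell matrix
    n_cells: int = 1000
    signature_size: int = 50  # regions per cellular-state signature
    stem_signature_size: int = 60
    stem_frac: float = 0.1
    depth_law: tuple[float, float] = (np.log(2000.0), 0.4)  # log-normal (meanlog, sdlog)
    effect_size: float = 2.0  # accessibility boost on signature regions
    gc_bias: float = 0.0  # couples GC with accessibility when > 0

    # expression
    n_genes: int = 2000
    de_frac: float = 0.1
    de_log2fc: float = 2.0
    expr_sigma: float = 0.5

    # survival
    baseline_hazard: float = 0.1  # events per time unit in the reference group
    state_hr: dict[str, float] = field(
        default_factory=lambda: {"Reactive": 1.0, "Constructive": 1.3, "Invasive": 3.5}
    )
    censor_time: float | None = 30.0
    # tumor cohort
    n_tumors: int = 144
    tumor_baseline_hazard: float = 0.02
    tumor_censor_time: float = 60.0
    tumor_expr_sigma: float = 0.8
    tumor_hr_scale: float = 0.5  # Invasive-weight gap carrying one full HR_Invasive

    # motifs
    n_motifs: int = 50
    n_planted_motifs: int = 5
    motif_base_rate: float = 0.1
    motif_rate_ratio: float = 4.0
    motif_target_size: int = 200
    motif_n_regions: int = 5000  # region universe; target kept a small fraction

    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "exclusive_frac": self.exclusive_frac,
            "shared_frac": self.shared_frac,
            "presence_prob": self.presence_prob,
            "stem_frac": self.stem_frac,
            "de_frac": self.de_frac,
            "motif_base_rate": self.motif_base_rate,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        counts = {
            "catalog_size": self.catalog_size,
            "n_cells": self.n_cells,
            "n_genes": self.n_genes,
            "n_motifs": self.n_motifs,
            "n_tumors": self.n_tumors,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if any(v <= 0 for v in self.samples_per_state.values()):
            raise ConfigError("samples_per_state counts must be positive")
        if any(hr <= 0 for hr in self.state_hr.values()):
            raise ConfigError("hazard ratios must be > 0")
        if self.exclusive_frac * len(self.samples_per_state) + self.shared_frac > 1:
            raise ConfigError("exclusive and shared fractions exceed the catalog")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class Truth:
    """Planted ground truth for one generator call."""

    sample_state: dict[str, str] = field(default_factory=dict)
    exclusive_regions: dict[str, set[int]] = field(default_factory=dict)
    cell_state: np.ndarray | None = None
    stem_flags: np.ndarray | None = None
    state_signature_regions: dict[str, np.ndarray] = field(default_factory=dict)
    stem_regions: np.ndarray | None = None
    de_genes: dict[str, set[str]] = field(default_factory=dict)
    planted_hr: dict[str, float] = field(default_factory=dict)
    invasive_weight: np.ndarray | None = None
    planted_motifs: list[str] = field(default_factory=list)
    motif_target_regions: np.ndarray | None = None
    motif_rate_ratio: float | None = None


def _states(cfg: SimConfig) -> list[str]:
    return sorted(cfg.samples_per_state)


def _region_roles(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Deterministic layout of the latent catalog into role blocks."""
    states = _states(cfg)
    n_excl = int(round(cfg.exclusive_frac * cfg.catalog_size))
    n_shared = int(round(cfg.shared_frac * cfg.catalog_size))
    pos = 0
    roles: dict[str, np.ndarray] = {}
    for s in states:
        roles[f"exclusive:{s}"] = np.arange(pos, pos + n_excl)
        pos += n_excl
    roles["shared"] = np.arange(pos, pos + n_shared)
    pos += n_shared
    roles["background"] = np.arange(pos, cfg.catalog_size)
    return roles


def _latent_interval(cfg: SimConfig, idx: int, jitter: int = 0) -> Interval:
    start = idx * cfg.region_spacing + jitter
    return Interval("chr1", max(0, start), max(0, start) + cfg.region_width)


def simulate_bulk_peaks(cfg: SimConfig, seed: int | None = None) -> tuple[list[SamplePeaks], Truth]:
    """Per-sample peak calls with planted state-exclusive region blocks.

    Each state's exclusive block is called (q below the strict filter) in
    every sample of that state; in other samples it is either absent or
    carries a weak call with q above the lenient filter. Shared regions are
    called in all samples; background regions are called per sample with
    ``presence_prob``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    roles = _region_roles(cfg)
    states = _states(cfg)
    samples: list[SamplePeaks] = []
    truth = Truth(
        exclusive_regions={s: set(roles[f"exclusive:{s}"].tolist()) for s in states},
        planted_hr=dict(cfg.state_hr),
    )
    i = 0
    for state in states:
        for _ in range(cfg.samples_per_state[state]):
            sid = f"GSC{i + 1:02d}"
            truth.sample_state[sid] = state
            present = np.zeros(cfg.catalog_size, dtype=bool)
            present[roles[f"exclusive:{state}"]] = True
            present[roles["shared"]] = True
            bg = roles["background"]
            present[bg[rng.random(len(bg)) < cfg.presence_prob]] = True
            absent = np.flatnonzero(~present)
            weak = absent[rng.random(len(absent)) < cfg.weak_call_prob]
            calls: list[PeakCall] = []
            for r in np.flatnonzero(present):
                iv = _latent_interval(cfg, int(r), int(rng.integers(-cfg.jitter, cfg.jitter + 1)))
                q = float(rng.uniform(*cfg.q_present))
                sig = float(rng.lognormal(cfg.signal_logmean, cfg.signal_logsd))
                calls.append(PeakCall(iv, q=q, signal=sig))
            for r in weak:
                iv = _latent_interval(cfg, int(r), int(rng.integers(-cfg.jitter, cfg.jitter + 1)))
                q = float(rng.uniform(*cfg.q_absent))
                sig = float(rng.lognormal(np.log(1.2), 0.3))
                calls.append(PeakCall(iv, q=q, signal=sig))
            calls.sort(key=lambda c: (c.interval.chrom, c.interval.start))
            samples.append(SamplePeaks(sample_id=sid, calls=calls, state=state))
            i += 1
    return samples, truth


def _cell_roles(cfg: SimConfig) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Signature blocks for the four cellular states and the stem block.

    Placed in the background portion of the latent catalog so they do not
    collide with the bulk state-exclusive blocks.
    """
    bg = _region_roles(cfg)["background"]
    need = len(CELL_STATES) * cfg.signature_size + cfg.stem_signature_size
    if len(bg) < need:
        raise ConfigError("catalog too small for the cellular-state signature blocks")
    blocks = {}
    pos = 0
    for s in CELL_STATES:
        blocks[s] = bg[pos : pos + cfg.signature_size]
        pos += cfg.signature_size
    stem = bg[pos : pos + cfg.stem_signature_size]
    return blocks, stem


def simulate_cell_matrix(cfg: SimConfig, seed: int | None = None) -> tuple[CellMatrix, Truth]:
    """Multinomial cell x region fragment counts with planted cell states.

    Per cell, the total depth is drawn from the log-normal ``depth_law`` and
    counts are multinomial over region probabilities; probabilities are
    multiplied by ``effect_size`` on the cell's state-signature block and,
    for stem cells, on the stem block. Depths are conserved exactly.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    blocks, stem = _cell_roles(cfg)
    n, r = cfg.n_cells, cfg.catalog_size
    gc = rng.uniform(0.3, 0.7, size=r)
    w = rng.gamma(2.0, 1.0, size=r)
    if cfg.gc_bias > 0:
        w = w * np.exp(cfg.gc_bias * (gc - 0.5) / 0.115)  # 0.115 ~ sd of U(0.3, 0.7)
    cell_state = rng.choice(CELL_STATES, size=n)
    stem_flags = rng.random(n) < cfg.stem_frac
    depth = np.maximum(np.round(rng.lognormal(*cfg.depth_law, size=n)), 100).astype(int)
    rows = []
    for c in range(n):
        wc = w.copy()
        wc[blocks[cell_state[c]]] *= cfg.effect_size
        if stem_flags[c]:
            wc[stem] *= cfg.effect_size
        rows.append(rng.multinomial(depth[c], wc / wc.sum()))
    counts = sp.csr_matrix(np.asarray(rows, dtype=np.int64))
    truth = Truth(
        cell_state=cell_state,
        stem_flags=stem_flags,
        state_signature_regions={s: blocks[s] for s in CELL_STATES},
        stem_regions=stem,
    )
    return CellMatrix(counts=counts, region_gc=gc), truth


def _gene_ids(cfg: SimConfig) -> list[str]:
    return [f"gene{i + 1:04d}" for i in range(cfg.n_genes)]


def _plant_centroids(cfg: SimConfig) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Per-state centroids on the log2(FPKM+1) scale with planted DE genes.

    Drawn from ``cfg.seed`` (not the per-call seed) so the reference cohort
    and tumor cohorts generated under one config share the same planted
    expression structure.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    states = _states(cfg)
    genes = _gene_ids(cfg)
    base = np.clip(rng.normal(3.0, 1.0, size=cfg.n_genes), 0.0, None)
    centroids = pd.DataFrame({s: base.copy() for s in states}, index=genes)
    n_de = int(round(cfg.de_frac * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    de_genes: dict[str, set[str]] = {s: set() for s in states}
    for j, g in enumerate(de_idx):
        s = states[j % len(states)]
        centroids.iloc[g, centroids.columns.get_loc(s)] += cfg.de_log2fc
        de_genes[s].add(genes[g])
    return centroids, de_genes


def simulate_expression(cfg: SimConfig, seed: int | None = None) -> tuple[pd.DataFrame, Truth]:
    """Reference GSC FPKM matrix (gene x sample) around planted centroids."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    centroids, de = _plant_centroids(cfg)
    cols, labels = [], {}
    data = {}
    i = 0
    for state in _states(cfg):
        for _ in range(cfg.samples_per_state[state]):
            sid = f"GSC{i + 1:02d}"
            logx = centroids[state].to_numpy() + rng.normal(0, cfg.expr_sigma, cfg.n_genes)
            data[sid] = np.clip(2.0**logx - 1.0, 0.0, None)
            cols.append(sid)
            labels[sid] = state
            i += 1
    expr = pd.DataFrame(data, index=centroids.index)
    truth = Truth(sample_state=labels, de_genes=de)
    return expr, truth


def simulate_tumor_cohort(
    cfg: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, list[SurvivalRecord], Truth]:
    """Tumor FPKM + survival where Invasive-like profiles carry higher hazard.

    Each tumor's log-expression is a convex mixture of the three planted
    state centroids; the Invasive mixture weight w ~ Beta(0.6, 2.5) (mostly
    low, a small tail of strongly Invasive tumors) also scales the hazard:
    baseline * HR_Invasive ** (w / tumor_hr_scale), so two tumors whose
    Invasive weights differ by ``tumor_hr_scale`` differ in hazard by the
    planted ratio. Censoring is administrative at ``tumor_censor_time``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    centroids, de = _plant_centroids(cfg)
    states = list(centroids.columns)
    hr_inv = cfg.state_hr.get("Invasive", max(cfg.state_hr.values()))
    w_inv = rng.beta(0.6, 2.5, size=cfg.n_tumors)
    alpha = rng.uniform(0.0, 1.0, size=cfg.n_tumors)  # Reactive-vs-Constructive balance
    data = {}
    records: list[SurvivalRecord] = []
    others = [s for s in states if s != "Invasive"] or states
    for i in range(cfg.n_tumors):
        tid = f"T{i + 1:03d}"
        mix = w_inv[i] * centroids.get("Invasive", centroids[states[0]]).to_numpy()
        rest = (1 - w_inv[i]) * (
            alpha[i] * centroids[others[0]].to_numpy()
            + (1 - alpha[i]) * centroids[others[-1]].to_numpy()
        )
        logx = mix + rest + rng.normal(0, cfg.tumor_expr_sigma, cfg.n_genes)
        data[tid] = np.clip(2.0**logx - 1.0, 0.0, None)
        hazard = cfg.tumor_baseline_hazard * hr_inv ** (w_inv[i] / cfg.tumor_hr_scale)
        t = float(rng.exponential(1.0 / hazard))
        if t >= cfg.tumor_censor_time:
            records.append(SurvivalRecord(tid, cfg.tumor_censor_time, 0, "cohort"))
        else:
            records.append(SurvivalRecord(tid, t, 1, "cohort"))
    expr = pd.DataFrame(data, index=centroids.index)
    truth = Truth(de_genes=de, planted_hr={"Invasive": hr_inv}, invasive_weight=w_inv)
    return expr, records, truth


def simulate_survival(
    cfg: SimConfig,
    seed: int | None = None,
    group_sizes: dict[str, int] | None = None,
) -> tuple[list[SurvivalRecord], Truth]:
    """Exponential event times with group hazard = baseline * HR[group].

    Administrative censoring at ``cfg.censor_time`` (None disables it;
    censor_time 0 censors every record at 0).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sizes = group_sizes if group_sizes is not None else dict(cfg.samples_per_state)
    unknown = set(sizes) - set(cfg.state_hr)
    if unknown:
        raise ConfigError(f"groups without a hazard ratio: {sorted(unknown)}")
    records: list[SurvivalRecord] = []
    i = 0
    for group in sorted(sizes):
        hazard = cfg.baseline_hazard * cfg.state_hr[group]
        times = rng.exponential(1.0 / hazard, size=sizes[group])
        for t in times:
            i += 1
            if cfg.censor_time is not None and t >= cfg.censor_time:
                records.append(SurvivalRecord(f"S{i:04d}", cfg.censor_time, 0, group))
            else:
                records.append(SurvivalRecord(f"S{i:04d}", float(t), 1, group))
    return records, Truth(planted_hr=dict(cfg.state_hr))


def simulate_motif_hits(cfg: SimConfig, seed: int | None = None) -> tuple[pd.DataFrame, Truth]:
    """Bernoulli region x motif hits with planted target-region enrichment.

    Planted motifs hit target regions at ``motif_base_rate * motif_rate_ratio``
    and all other regions at the base rate; the remaining motifs are null.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    motifs = [f"M{j + 1:03d}" for j in range(cfg.n_motifs)]
    planted = motifs[: cfg.n_planted_motifs]
    n_regions = cfg.motif_n_regions
    target = np.arange(min(cfg.motif_target_size, n_regions))
    rates = np.full((n_regions, cfg.n_motifs), cfg.motif_base_rate)
    boosted = min(cfg.motif_base_rate * cfg.motif_rate_ratio, 1.0)
    rates[np.ix_(target, np.arange(cfg.n_planted_motifs))] = boosted
    hits = rng.random((n_regions, cfg.n_motifs)) < rates
    truth = Truth(
        planted_motifs=planted,
        motif_target_regions=target,
        motif_rate_ratio=cfg.motif_rate_ratio,
    )
    return pd.DataFrame(hits, columns=motifs), truth
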