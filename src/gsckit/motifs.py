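"""PWM motif scanning and motif-family enrichment of region sets.

A transparent log-odds scanner (uniform 0.25 background, both strands)
produces binary region x motif hits; enrichment of a target set (e.g. the
regions exclusively accessible in one GSC state) is tested against the full
peak catalog as background with an upper-tail hypergeometric test and BH
correction. Motifs are grouped into DNA-binding-domain families; each family
is assigned the fold enrichment of its most enriched significant motif, and
families are retained above a log2 fold-enrichment threshold.

Note: this scanner and hypergeometric model are a deliberately simple,
fully specified alternative to HOMER's ZOOPS/binomial machinery; outputs
carry a ``method`` tag so results are not conflated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["PWM", "scan_motifs", "enrich_motifs", "family_scores"]

_BASES = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position weight matrix: 4 x L base probabilities (rows A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray
    family: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValueError("matrix must be 4 x L")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"columns of {self.motif_id} must sum to 1")
        self.matrix = m

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self, pseudocount: float = 1e-3) -> np.ndarray:
        p = (self.matrix + pseudocount) / (1 + 4 * pseudocount)
        return np.log2(p / 0.25)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASES.get(c, 4) for c in seq.upper()), dtype=np.int8, count=len(seq))


def _best_score(enc: np.ndarray, lo: np.ndarray) -> float:
    """Best sliding-window log-odds score; N (code 4) scores 0 (background)."""
    L = lo.shape[1]
    n = len(enc) - L + 1
    if n <= 0:
        return -np.inf
    padded = np.vstack([lo, np.zeros(L)])  # row 4 = N -> score 0
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    scores = padded[windows, np.arange(L)].sum(axis=1)
    return float(scores.max())


def scan_motifs(
    sequences: list[str],
    pwms: list[PWM],
    rel_threshold: float = 0.8,
    pseudocount: float = 1e-3,
) -> pd.DataFrame:
    """Binary region x motif hit matrix from a both-strand log-odds scan.

    A region is hit iff its best window score on either strand reaches
    ``rel_threshold`` times the motif's maximum attainable score. Sequences
    shorter than a motif cannot hit it (warned once).
    """
    hits = np.zeros((len(sequences), len(pwms)), dtype=bool)
    encoded = [ _encode(s) for s in sequences ]
    rc_encoded = [ _encode(s.upper().translate(_COMPLEMENT)[::-1]) for s in sequences ]
    short_warned = False
    for j, pwm in enumerate(pwms):
        lo = pwm.log_odds(pseudocount)
        max_score = lo.max(axis=0).sum()
        cutoff = rel_threshold * max_score
        for i, (enc, rc) in enumerate(zip(encoded, rc_encoded)):
            if len(enc) < pwm.length:
                if not short_warned:
                    warnings.warn("sequence shorter than motif: no hit possible", RuntimeWarning)
                    short_warned = True
                continue
            if _best_score(enc, lo) >= cutoff or _best_score(rc, lo) >= cutoff:
                hits[i, j] = True
    return pd.DataFrame(hits, columns=[p.motif_id for p in pwms])


def enrich_motifs(
    hits: pd.DataFrame,
    target_regions,
    catalog_regions=None,
    families: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-motif fold enrichment of a target region set vs the catalog.

    FE = (target hit rate) / (catalog hit rate); p is the upper-tail
    hypergeometric probability of the target hit count given catalog totals;
    q is BH across motifs. Motifs without catalog hits get FE = NaN and are
    flagged.
    """
    target = np.asarray(sorted(set(map(int, target_regions))), dtype=int)
    if catalog_regions is None:
        catalog = np.arange(len(hits))
    else:
        catalog = np.asarray(sorted(set(map(int, catalog_regions))), dtype=int)
    if not set(target) <= set(catalog):
        raise ValueError("target regions must be a subset of the catalog")
    H = hits.to_numpy(dtype=bool)
    n_t, n_cat = len(target), len(catalog)
    hits_t = H[target].sum(axis=0)
    hits_cat = H[catalog].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fe = np.where(hits_cat > 0, (hits_t / n_t) / (hits_cat / n_cat), np.nan)
    p = stats.hypergeom.sf(hits_t - 1, n_cat, hits_cat, n_t)
    p = np.where(hits_cat > 0, p, np.nan)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "motif_id": hits.columns,
            "family": [families.get(m) if families else None for m in hits.columns],
            "hits_target": hits_t,
            "hits_catalog": hits_cat,
            "fold_enrichment": fe,
            "p": p,
            "q": q,
            "flagged": hits_cat == 0,
        }
    )
    out.attrs["method"] = "log-odds scan + hypergeometric (catalog background)"
    return out


def family_scores(
    rows: pd.DataFrame, min_log2fe: float = 0.5, q: float = 0.05
) -> dict[str, float]:
    """Family score = max fold enrichment over significant member motifs.

    Only motifs with q <= ``q`` count; families are retained iff
    log2(score) > ``min_log2fe``. Families with no significant member are
    absent from the output.
    """
    if "family" not in rows or rows["family"].isna().all():
        raise ValueError("rows must carry family annotations")
    sig = rows[(rows["q"] <= q) & rows["fold_enrichment"].notna() & rows["family"].notna()]
    scores = sig.groupby("family")["fold_enrichment"].max()
    kept = scores[np.log2(scores.clip(lower=1e-300)) > min_log2fe]
    return {str(f): float(v) for f, v in kept.items()}
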