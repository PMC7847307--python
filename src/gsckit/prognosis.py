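"""Tumor stratification by concordance with GSC-state expression centroids.

Per-state marker genes are the rank-sum/BH differentially expressed genes
(q <= 0.05, fold change >= 2) of the reference GSC cohort, optionally
intersected with genes whose promoters lie in state-exclusive accessible
regions. State centroids are mean log2(FPKM+1) profiles over the DE-gene
union. Each tumor is scored against each centroid with a pairwise
rank-concordance index (fraction of gene pairs ordered the same way, ties
counted half) and assigned to the argmax state. The cohort's Invasive
concordance column is z-scored and binned (low < 1, mid 1-1.65, high >=
1.65); survival differences between bins are assessed with Kaplan-Meier,
log-rank and Cox models from :mod:`gsckit.survival`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "de_genes",
    "exclusive_state_genes",
    "state_centroids",
    "concordance_index",
    "concordance_scores",
    "assign_state",
    "invasive_bins",
]


def de_genes(
    expr: pd.DataFrame,
    state_labels: dict[str, str] | list[str],
    q: float = 0.05,
    fc: float = 2.0,
) -> dict[str, set[str]]:
    """Per-state up-regulated genes: rank-sum on log2(FPKM+1), BH, FC filter.

    ``expr`` is gene x sample FPKM. A gene belongs to a state's set iff its
    BH-adjusted rank-sum q <= ``q``, its mean-FPKM ratio state/rest >= ``fc``
    (boundary inclusive), and the state mean is higher.
    """
    if isinstance(state_labels, dict):
        labels = np.array([state_labels[s] for s in expr.columns], dtype=object)
    else:
        labels = np.asarray(state_labels, dtype=object)
    if len(labels) != expr.shape[1]:
        raise ValueError("one state label per sample required")
    logx = np.log2(expr.to_numpy(dtype=float) + 1.0)
    out: dict[str, set[str]] = {}
    for state in sorted(set(map(str, labels))):
        in_state = labels == state
        if in_state.sum() < 2 or (~in_state).sum() < 2:
            raise ValueError(f"state {state!r} needs >= 2 samples on each side")
        a, b = logx[:, in_state], logx[:, ~in_state]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(a, b, axis=1, method="asymptotic")
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        mean_a = expr.to_numpy(dtype=float)[:, in_state].mean(axis=1)
        mean_b = expr.to_numpy(dtype=float)[:, ~in_state].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(mean_b > 0, mean_a / mean_b, np.where(mean_a > 0, np.inf, 0.0))
        keep = (qvals <= q) & (ratio >= fc) & (mean_a > mean_b)
        out[state] = set(expr.index[keep])
    return out


def exclusive_state_genes(
    de_sets: dict[str, set[str]],
    exclusive_promoter_genes: dict[str, set[str]],
) -> dict[str, set[str]]:
    """Genes DE-up in a state whose promoter is exclusively accessible there."""
    if set(de_sets) != set(exclusive_promoter_genes):
        raise ValueError("inputs must be keyed by the same states")
    out = {s: de_sets[s] & exclusive_promoter_genes[s] for s in de_sets}
    seen: set[str] = set()
    for s, genes in sorted(out.items()):
        overlap = seen & genes
        assert not overlap, f"gene in two exclusive sets: {sorted(overlap)}"
        seen |= genes
    return out


def state_centroids(
    expr_reference: pd.DataFrame,
    state_labels: dict[str, str] | list[str],
    genes: list[str],
) -> pd.DataFrame:
    """Gene x state mean log2(FPKM+1) centroids over the DE-gene union."""
    missing = sorted(set(genes) - set(expr_reference.index))
    if missing:
        raise KeyError(f"genes missing from expression matrix: {missing}")
    if isinstance(state_labels, dict):
        labels = [state_labels[s] for s in expr_reference.columns]
    else:
        labels = list(state_labels)
    logx = np.log2(expr_reference.loc[list(genes)].astype(float) + 1.0)
    return logx.T.groupby(np.asarray(labels, dtype=object)).mean().T


def concordance_index(sample_vector, centroid_vector) -> float:
    """Pairwise rank concordance of two profiles over the same genes.

    Over all gene pairs (i, j): concordant if the two profiles order the
    pair the same way; a pair tied in either profile counts half. Invariant
    under strictly increasing transforms of either vector.
    """
    s = np.asarray(sample_vector, dtype=float)
    c = np.asarray(centroid_vector, dtype=float)
    if s.shape != c.shape or s.ndim != 1:
        raise ValueError("vectors must be 1-D and equally long")
    n = len(s)
    if n < 2:
        raise ValueError("need >= 2 genes")
    ds = np.sign(s[:, None] - s[None, :])
    dc = np.sign(c[:, None] - c[None, :])
    prod = ds * dc
    iu = np.triu_indices(n, k=1)
    prod = prod[iu]
    tied = (ds[iu] == 0) | (dc[iu] == 0)
    concordant = (prod > 0).sum()
    return float((concordant + 0.5 * tied.sum()) / len(prod))


def concordance_scores(
    tumor_expr: pd.DataFrame, centroids: pd.DataFrame
) -> pd.DataFrame:
    """Sample x state concordance indices of tumors vs state centroids.

    ``tumor_expr`` is gene x sample FPKM; profiles are compared on the
    centroid gene set after log2(FPKM+1) (which, being monotone, does not
    change the concordance).
    """
    genes = list(centroids.index)
    missing = sorted(set(genes) - set(tumor_expr.index))
    if missing:
        raise KeyError(f"genes missing from tumor matrix: {missing}")
    logx = np.log2(tumor_expr.loc[genes].astype(float) + 1.0)
    out = pd.DataFrame(
        {
            state: [
                concordance_index(logx[s].to_numpy(), centroids[state].to_numpy())
                for s in tumor_expr.columns
            ]
            for state in centroids.columns
        },
        index=tumor_expr.columns,
    )
    return out


def assign_state(C: pd.DataFrame) -> pd.DataFrame:
    """Assign each sample to the argmax-concordance state; flag exact ties.

    Ties break by state name order (alphabetical first).
    """
    states = sorted(C.columns)
    vals = C[states].to_numpy(dtype=float)
    best = vals.argmax(axis=1)  # argmax takes the first (alphabetical) on ties
    tie = (vals == vals.max(axis=1, keepdims=True)).sum(axis=1) > 1
    return pd.DataFrame(
        {"state": [states[i] for i in best], "tie": tie}, index=C.index
    )


def invasive_bins(
    c_invasive: pd.Series, low: float = 1.0, high: float = 1.65
) -> pd.DataFrame:
    """Bin the cohort by the z-score of its Invasive concordance column.

    z < ``low`` -> "low"; ``low`` <= z < ``high`` -> "mid"; z >= ``high`` ->
    "high" (sample standard deviation). Raises on zero spread.
    """
    c = pd.Series(c_invasive, dtype=float)
    if len(c) < 3:
        raise ValueError("cohort must have >= 3 samples")
    sd = c.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero standard deviation: cannot z-score cohort")
    z = (c - c.mean()) / sd
    bins = pd.cut(
        z, bins=[-np.inf, low, high, np.inf], right=False, labels=["low", "mid", "high"]
    ).astype(str)
    return pd.DataFrame({"z": z, "bin": bins}, index=c.index)
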