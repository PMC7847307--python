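"""CRISPR-screen essentiality: Bayes-factor normalization and exclusive sets.

Gene x line Bayes factors (BAGEL-style; larger = stronger depletion on
knockout) come with per-line empirically determined essentiality thresholds
(derived upstream from a 5% FDR). For cross-line display and comparison the
scores are scaled per line (divided by the line's BF standard deviation)
after subtracting its threshold, putting the essentiality cut-off at 0 in
every line. A gene is called essential in a line iff its raw BF reaches both
the global minimum (BF >= 3) and the line's threshold, and is exclusive to a
GSC state iff essential in at least one of that state's lines and in none of
any other state's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EssentialCalls", "normalize_bf", "call_essential", "state_exclusive_essentials"]


@dataclass
class EssentialCalls:
    calls: pd.DataFrame  # boolean gene x line
    scaled: pd.DataFrame  # gene x line, common threshold at 0
    min_bf: float


def _check_thresholds(bf: pd.DataFrame, line_threshold: dict[str, float]) -> None:
    missing = set(bf.columns) - set(line_threshold)
    if missing:
        raise ValueError(f"missing thresholds for lines: {sorted(missing)}")
    bad = [l for l, t in line_threshold.items() if not np.isfinite(t)]
    if bad:
        raise ValueError(f"non-finite thresholds for lines: {bad}")


def normalize_bf(bf: pd.DataFrame, line_threshold: dict[str, float]) -> pd.DataFrame:
    """Per line: scaled = (BF - threshold) / sd(BF); threshold maps to 0."""
    _check_thresholds(bf, line_threshold)
    out = {}
    for line in bf.columns:
        sd = float(bf[line].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"line {line!r} has zero BF standard deviation")
        out[line] = (bf[line] - line_threshold[line]) / sd
    return pd.DataFrame(out, index=bf.index)


def call_essential(
    bf: pd.DataFrame, line_threshold: dict[str, float], min_bf: float = 3.0
) -> EssentialCalls:
    """Essential iff BF >= max(min_bf, line threshold); boundary inclusive."""
    _check_thresholds(bf, line_threshold)
    cut = {l: max(min_bf, line_threshold[l]) for l in bf.columns}
    calls = pd.DataFrame({l: bf[l] >= cut[l] for l in bf.columns}, index=bf.index)
    return EssentialCalls(calls=calls, scaled=normalize_bf(bf, line_threshold), min_bf=min_bf)


def state_exclusive_essentials(
    calls: EssentialCalls | pd.DataFrame, line_state: dict[str, str]
) -> dict[str, set[str]]:
    """Genes essential in >= 1 line of one state and in no line of any other."""
    mat = calls.calls if isinstance(calls, EssentialCalls) else calls
    unlabeled = set(mat.columns) - set(line_state)
    if unlabeled:
        raise ValueError(f"lines without a state label: {sorted(unlabeled)}")
    states = sorted(set(line_state[l] for l in mat.columns))
    per_state = {
        s: mat[[l for l in mat.columns if line_state[l] == s]].any(axis=1) for s in states
    }
    out: dict[str, set[str]] = {}
    for s in states:
        others = pd.concat([per_state[t] for t in states if t != s], axis=1)
        none_elsewhere = ~others.any(axis=1) if others.shape[1] else pd.Series(True, index=mat.index)
        out[s] = set(mat.index[per_state[s] & none_elsewhere])
    return out
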