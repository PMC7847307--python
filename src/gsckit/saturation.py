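"""Peak-discovery saturation: rarefaction curves and asymptotic regression.

The cohort's completeness is estimated by randomizing sample order, counting
the cumulative number of distinct peaks as samples are added one by one,
averaging over many permutations, and fitting an asymptotic regression
y(n) = A * (1 - exp(-k * n)) whose asymptote A predicts the total number of
accessible regions discoverable from the population the cohort samples.
The saturation fraction is the observed total divided by A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["DiscoveryCurve", "SaturationFit", "discovery_curve", "fit_saturation"]


@dataclass
class DiscoveryCurve:
    """Permutation-averaged cumulative distinct-peak counts per added sample."""

    mean_cumulative: np.ndarray  # length n_samples; mean_cumulative[i] after i+1 samples
    n_perm: int

    def __post_init__(self) -> None:
        y = np.asarray(self.mean_cumulative, dtype=float)
        if np.any(np.diff(y) < -1e-9):
            raise ValueError("cumulative discovery curve must be non-decreasing")
        self.mean_cumulative = y

    @property
    def n_samples(self) -> int:
        return len(self.mean_cumulative)


@dataclass
class SaturationFit:
    asymptote: float  # predicted total region count A
    rate: float  # exponential rate k per added sample
    saturation_fraction: float  # observed total / A
    rss: float
    model: str = "asymptotic_exponential"

    def __post_init__(self) -> None:
        if not 0.0 < self.saturation_fraction <= 1.0 + 1e-12:
            raise ValueError("saturation fraction must lie in (0, 1]")


def discovery_curve(
    occupancy: np.ndarray, n_perm: int = 10_000, seed: int | None = None
) -> DiscoveryCurve:
    """Mean cumulative distinct-peak count over random sample orders.

    ``occupancy`` is a boolean sample x region matrix. For each permutation
    of the rows, the cumulative number of distinct occupied regions is
    recorded after each added sample; the curve is the average over
    ``n_perm`` permutations. The last value is the total distinct count and
    is identical for every permutation.
    """
    occ = np.asarray(occupancy, dtype=bool)
    if occ.size == 0:
        raise ValueError("occupancy matrix is empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_s, _ = occ.shape
    rng = np.random.default_rng(seed)
    any_occ = occ.any(axis=0)
    total = np.zeros(n_s)
    for _ in range(n_perm):
        perm = rng.permutation(n_s)
        # first permuted sample occupying each region -> increment at that step
        first = occ[perm].argmax(axis=0)
        counts = np.bincount(first[any_occ], minlength=n_s)
        total += np.cumsum(counts)
    return DiscoveryCurve(mean_cumulative=total / n_perm, n_perm=n_perm)


def _model(n: np.ndarray, a: float, k: float) -> np.ndarray:
    return a * (1.0 - np.exp(-k * n))


def fit_saturation(curve: DiscoveryCurve, model: str = "asymptotic_exponential") -> SaturationFit:
    """Least-squares asymptotic regression of the discovery curve.

    Self-starting: A0 = 1.05 * max(y); k0 from a log-linear regression of
    log(1 - y/A0) on n. ``model`` may be "asymptotic_exponential" (default,
    y = A(1 - exp(-kn))) or "michaelis_menten" (y = A n / (K + n)) for
    sensitivity analysis. A flat curve is degenerate: A equals the observed
    total and the fraction is 1.
    """
    y = curve.mean_cumulative
    n = np.arange(1, len(y) + 1, dtype=float)
    if len(y) < 3:
        raise ValueError("need >= 3 points to fit saturation")
    y_obs = y[-1]
    if np.allclose(y, y_obs):
        return SaturationFit(asymptote=y_obs, rate=np.inf, saturation_fraction=1.0, rss=0.0, model=model)

    a0 = 1.05 * float(y.max())
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.log(np.clip(1.0 - y / a0, 1e-12, None))
    slope = np.polyfit(n, resid, 1)[0]
    k0 = max(-slope, 1e-6)

    if model == "asymptotic_exponential":
        fun = _model
        p0 = (a0, k0)
    elif model == "michaelis_menten":
        fun = lambda nn, a, km: a * nn / (km + nn)  # noqa: E731
        p0 = (a0, max(1.0 / k0, 1e-6))
    else:
        raise ValueError(f"unknown model {model!r}")

    try:
        popt, _ = curve_fit(
            fun, n, y, p0=p0,
            bounds=([y_obs, 1e-12], [np.inf, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"saturation fit did not converge: {err}") from err
    a_hat, k_hat = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - fun(n, *popt)) ** 2))
    return SaturationFit(
        asymptote=a_hat,
        rate=k_hat,
        saturation_fraction=float(min(y_obs / a_hat, 1.0)),
        rss=rss,
        model=model,
    )
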