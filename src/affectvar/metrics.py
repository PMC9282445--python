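"""Classic summary measures of affective variability.

These are the standard instability metrics reported alongside the filter:
the sample mean and SD, the root mean square of successive differences
(RMSSD), sample entropy, the Teager–Kaiser energy operator (TKEO), and the
lag-1 autoregressive (AR1) "inertia" model. All of them quantify *how much*
ratings fluctuate, but none distinguishes persistent change (volatility)
from transient change (noise): simulations in the test-suite show every one
of them rises under either cause.

Missing-day policy: difference-based metrics (RMSSD, TKEO, AR1) use only
pairs/triples of ratings on consecutive calendar days — gaps are never
bridged, so missingness is not conflated with variability. Sample entropy
is computed on the longest run of consecutive observed days.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateRegressorError, InsufficientDataError
from .model import FilterTrajectory
from .series import RatingSeries

#: Sentinel returned when sample entropy is undefined (no template matches).
ENTROPY_UNDEFINED = math.inf


def summary_moments(series: RatingSeries) -> tuple[float, float]:
    """Sample mean and SD (denominator n-1) of the observed ratings."""
    v = series.observed_values
    if v.size < 2:
        raise InsufficientDataError("need at least 2 observed ratings for mean/SD")
    return float(v.mean()), float(v.std(ddof=1))


def rmssd(series: RatingSeries) -> float:
    """Root mean square of successive differences on consecutive days.

    Pairs that span a missing day are excluded rather than bridged.
    """
    pairs = series.consecutive_pairs()
    if pairs.shape[0] == 0:
        raise InsufficientDataError("no ratings on consecutive days")
    d = pairs[:, 1] - pairs[:, 0]
    return float(np.sqrt(np.mean(d**2)))


def tkeo_mean(series: RatingSeries) -> float:
    """Mean Teager–Kaiser energy, Psi_t = y_t^2 - y_{t-1} * y_{t+1}.

    Computed at interior points of runs of >= 3 consecutive observed days.
    """
    psis = []
    for run in series.consecutive_runs():
        if run.size >= 3:
            psis.append(run[1:-1] ** 2 - run[:-2] * run[2:])
    if not psis:
        raise InsufficientDataError("no run of 3 consecutive observed days")
    return float(np.mean(np.concatenate(psis)))


def _sampen(x: np.ndarray, m: int, r: float) -> float:
    """Sample entropy of a 1-D array by direct template counting."""
    n = x.size
    if n < m + 2:
        raise InsufficientDataError(f"need at least m + 2 = {m + 2} points")

    def count(mm: int) -> int:
        t = np.lib.stride_tricks.sliding_window_view(x, mm)
        # Chebyshev distance between all template pairs, self-matches excluded
        d = np.abs(t[:, None, :] - t[None, :, :]).max(axis=2)
        iu = np.triu_indices(len(t), k=1)
        return int((d[iu] <= r).sum())

    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        return ENTROPY_UNDEFINED
    return float(-math.log(a / b))


def entropy(series: RatingSeries, m: int = 2, r: float | None = None) -> float:
    """Sample entropy of the longest run of consecutive observed days.

    Parameters
    ----------
    m : int
        Embedding (template) length; matches are counted at lengths m and
        m + 1 with Chebyshev distance.
    r : float, optional
        Match tolerance in rating units; defaults to 0.2 x the SD of the
        run. A constant run has zero entropy by convention; if no template
        pair matches, the explicit sentinel :data:`ENTROPY_UNDEFINED`
        (+inf) is returned instead of a silent NaN.
    """
    runs = [run for run in series.consecutive_runs()]
    if not runs:
        raise InsufficientDataError("no observed ratings")
    x = max(runs, key=len)
    if x.size < m + 2:
        raise InsufficientDataError(
            f"longest consecutive run has {x.size} < m + 2 = {m + 2} points"
        )
    sd = float(x.std())
    if np.ptp(x) <= 1e-12:  # (numerically) constant: perfectly regular
        return 0.0
    if r is None:
        r = 0.2 * sd
    return _sampen(x, m, r)


def ar1_fit(series: RatingSeries) -> tuple[float, float]:
    """AR(1) inertia: OLS slope of y_t on y_{t-1} plus residual SD.

    Fit with intercept over consecutive-day pairs; the residual SD uses
    denominator (n_pairs - 2). The slope is the classic emotional-inertia
    measure, and the residual SD its companion noise measure.
    """
    pairs = series.consecutive_pairs()
    if pairs.shape[0] < 3:
        raise InsufficientDataError("need at least 3 consecutive-day pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateRegressorError("lagged ratings are constant")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    resid_sd = float(np.sqrt((resid**2).sum() / (len(resid) - 2)))
    return float(slope), resid_sd


@dataclass
class VariabilityMetrics:
    """One row of endpoint metrics for a participant x valence series."""

    participant_id: str
    valence: str
    mean: float
    sd: float
    rmssd: float
    entropy: float
    tkeo: float
    ar1_slope: float
    ar1_resid_sd: float
    volatility: float | None = None
    noise: float | None = None


def variability_table(
    series: Sequence[RatingSeries],
    trajectories: Sequence[FilterTrajectory] | None = None,
    entropy_m: int = 2,
    entropy_r: float | None = None,
) -> pd.DataFrame:
    """Compute all metrics for many series; optionally join filter endpoints.

    ``trajectories`` (if given) must be positionally aligned with ``series``;
    the final-day posterior volatility and noise are taken as the
    filter-derived columns. Metrics that cannot be computed for a series
    (too few consecutive observations) are reported as NaN.
    """
    if trajectories is not None and len(trajectories) != len(series):
        raise InsufficientDataError("trajectories must align with series")
    rows = []
    for idx, s in enumerate(series):
        def _try(f, *a):
            try:
                return f(s, *a)
            except InsufficientDataError:
                return math.nan

        mean_sd = _try(summary_moments)
        mean, sd = mean_sd if isinstance(mean_sd, tuple) else (math.nan, math.nan)
        ar = _try(ar1_fit)
        slope, resid = ar if isinstance(ar, tuple) else (math.nan, math.nan)
        row = VariabilityMetrics(
            participant_id=s.participant_id,
            valence=s.valence,
            mean=mean,
            sd=sd,
            rmssd=_try(rmssd),
            entropy=_try(entropy, entropy_m, entropy_r),
            tkeo=_try(tkeo_mean),
            ar1_slope=slope,
            ar1_resid_sd=resid,
        )
        if trajectories is not None:
            row.volatility = float(trajectories[idx].volatility[-1])
            row.noise = float(trajectories[idx].noise[-1])
        rows.append(row)
    return pd.DataFrame([r.__dict__ for r in rows])
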