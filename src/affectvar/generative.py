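"""Forward simulator of the hierarchical generative model of affect.

The model assumes one rating per day, drawn from a Gaussian whose mean
``mu_t`` drifts as a random walk. Two latent scales govern the two kinds of
variability:

* **volatility** ``vmu_t`` — the SD of the mean's per-day innovation; a
  volatile period produces changes of affect that persist, because every
  later rating inherits the shifted mean;
* **noise** ``SD_t`` — the observation SD around the mean; a noisy period
  produces transient, day-local excursions.

Both scales themselves evolve as Gaussian random walks in log space (which
keeps them positive), with static per-subject rates ``kmu`` (for
log-volatility) and ``vsd`` (for log-noise)::

    log vmu_t = log vmu_{t-1} + N(0, kmu^2)
    log SD_t  = log SD_{t-1}  + N(0, vsd^2)
    mu_t      = mu_{t-1}      + N(0, vmu_{t-1}^2)
    y_t       ~ N(mu_t, SD_t^2), clipped to the rating-scale bounds

The innovation of ``mu_t`` uses the volatility *before* the step so that
one-step-ahead prediction in the filter is causal. Ratings are clipped (not
truncated-Gaussian resampled) to the scale bounds; the latent mean is left
unbounded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ParameterizationError, ScheduleError
from .series import RatingSeries


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of one subject's affect process.

    Attributes
    ----------
    mu0 : float
        Initial latent mean, in rating units.
    vmu0 : float
        Initial volatility: SD of the mean's per-day innovation (rating units).
    sd0 : float
        Initial observation-noise SD (rating units).
    kmu : float
        SD of the per-day innovations of log-volatility (dimensionless).
    vsd : float
        SD of the per-day innovations of log-noise (dimensionless).
    n_steps : int
        Number of days to simulate.
    bounds : (float, float)
        Rating-scale interval; emitted ratings are clipped to it.
    """

    mu0: float
    vmu0: float
    sd0: float
    kmu: float = 0.0
    vsd: float = 0.0
    n_steps: int = 50
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not self.vmu0 > 0:
            raise ParameterizationError("vmu0", f"must be > 0, got {self.vmu0}")
        if not self.sd0 > 0:
            raise ParameterizationError("sd0", f"must be > 0, got {self.sd0}")
        if self.kmu < 0:
            raise ParameterizationError("kmu", f"must be >= 0, got {self.kmu}")
        if self.vsd < 0:
            raise ParameterizationError("vsd", f"must be >= 0, got {self.vsd}")
        if self.n_steps < 2:
            raise ParameterizationError("n_steps", f"must be >= 2, got {self.n_steps}")
        lo, hi = self.bounds
        if not lo < hi:
            raise ParameterizationError("bounds", f"must satisfy lo < hi, got {self.bounds}")


@dataclass
class LatentTrajectory:
    """True per-day latent states of a simulated subject."""

    mu: np.ndarray
    vmu: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.mu) == len(self.vmu) == len(self.sd)):
            raise ParameterizationError("mu/vmu/sd", "latent sequences must share a length")
        if np.any(self.vmu <= 0) or np.any(self.sd <= 0):
            raise ParameterizationError("vmu/sd", "latent scales must stay positive")


@dataclass(frozen=True)
class RegimeSegment:
    start_day: int
    end_day: int
    vmu_level: float
    sd_level: float


@dataclass
class RegimeSchedule:
    """Piecewise-constant volatility/noise levels over ``[1, n_steps]``.

    Segments must be contiguous and non-overlapping; levels are the exact
    values of ``vmu_t`` and ``SD_t`` within each segment (the log random
    walks are overridden).
    """

    segments: list[RegimeSegment]
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.segments = [RegimeSegment(*s) if not isinstance(s, RegimeSegment) else s
                         for s in self.segments]
        if not self.segments:
            raise ScheduleError("schedule must contain at least one segment")
        segs = sorted(self.segments, key=lambda s: s.start_day)
        if segs[0].start_day != 1:
            raise ScheduleError("first segment must start on day 1")
        for a, b in zip(segs, segs[1:]):
            if b.start_day != a.end_day + 1:
                raise ScheduleError(
                    f"gap or overlap between day {a.end_day} and day {b.start_day}"
                )
        for s in segs:
            if s.end_day < s.start_day:
                raise ScheduleError(f"segment ({s.start_day}, {s.end_day}) is empty")
            if s.vmu_level <= 0 or s.sd_level <= 0:
                raise ScheduleError("all volatility/noise levels must be > 0")
        self.segments = segs

    @property
    def n_steps(self) -> int:
        return self.segments[-1].end_day

    def levels(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand segments into per-day (vmu, sd) arrays of length n_steps."""
        vmu = np.empty(self.n_steps)
        sd = np.empty(self.n_steps)
        for s in self.segments:
            vmu[s.start_day - 1 : s.end_day] = s.vmu_level
            sd[s.start_day - 1 : s.end_day] = s.sd_level
        return vmu, sd


#: Levels used by :func:`demo_regime_schedule`; overridable via its arguments.
DEMO_LEVELS = {"vmu_high": 0.05, "vmu_low": 0.005, "sd_high": 0.10, "sd_low": 0.02}


def demo_regime_schedule(
    vmu_high: float = DEMO_LEVELS["vmu_high"],
    vmu_low: float = DEMO_LEVELS["vmu_low"],
    sd_high: float = DEMO_LEVELS["sd_high"],
    sd_low: float = DEMO_LEVELS["sd_low"],
    bounds: tuple[float, float] = (0.0, 1.0),
) -> RegimeSchedule:
    """The 360-day benchmark schedule used to demonstrate the filter.

    Volatility is high on days 1–120 and 301–360 and low on 121–300; noise is
    high on days 61–120 and 241–360 and low on 1–60 and 121–240. Ratings live
    on [0, 1]. Exercises every combination of high/low volatility and noise.
    """
    return RegimeSchedule(
        segments=[
            RegimeSegment(1, 60, vmu_high, sd_low),
            RegimeSegment(61, 120, vmu_high, sd_high),
            RegimeSegment(121, 240, vmu_low, sd_low),
            RegimeSegment(241, 300, vmu_low, sd_high),
            RegimeSegment(301, 360, vmu_high, sd_high),
        ],
        bounds=bounds,
    )


def _walk_and_observe(
    mu0: float,
    vmu: np.ndarray,
    sd: np.ndarray,
    bounds: tuple[float, float],
    rng: np.random.Generator,
    participant_id: str,
    valence: str,
) -> tuple[np.ndarray, RatingSeries]:
    """Random-walk the mean along given scale paths and emit clipped ratings.

    The latent mean reflects at the rating-scale bounds (implemented by
    folding the free walk into the interval, which is the exact reflected
    walk). Without reflection a long series can saturate at a scale edge,
    where every rating clips and the diary carries no signal — unlike any
    plausible affect series. Pass very wide bounds to recover the free walk.
    """
    n = len(vmu)
    mu = np.empty(n)
    mu[0] = mu0
    # innovation at step t uses vmu_{t-1}
    mu[1:] = mu0 + np.cumsum(rng.normal(0.0, 1.0, size=n - 1) * vmu[:-1])
    lo_, hi_ = bounds
    r = hi_ - lo_
    z = np.mod(mu - lo_, 2.0 * r)
    mu = lo_ + (r - np.abs(r - z))
    y = rng.normal(mu, sd)
    lo, hi = bounds
    series = RatingSeries(
        participant_id=participant_id,
        valence=valence,
        days=np.arange(1, n + 1),
        values=np.clip(y, lo, hi),
        bounds=bounds,
    )
    return mu, series


def simulate_subject(
    params: GenerativeParams,
    seed: int | np.random.SeedSequence,
    participant_id: str = "sim",
    valence: str = "positive",
) -> tuple[LatentTrajectory, RatingSeries]:
    """Simulate one subject's latent trajectory and observed ratings.

    The same ``(params, seed)`` pair always yields bit-identical output.
    """
    rng = np.random.default_rng(seed)
    n = params.n_steps
    log_vmu = math.log(params.vmu0) + np.concatenate(
        [[0.0], np.cumsum(rng.normal(0.0, 1.0, size=n - 1) * params.kmu)]
    )
    log_sd = math.log(params.sd0) + np.concatenate(
        [[0.0], np.cumsum(rng.normal(0.0, 1.0, size=n - 1) * params.vsd)]
    )
    vmu = np.exp(log_vmu)
    sd = np.exp(log_sd)
    mu, series = _walk_and_observe(
        params.mu0, vmu, sd, params.bounds, rng, participant_id, valence
    )
    return LatentTrajectory(mu=mu, vmu=vmu, sd=sd), series


def simulate_regimes(
    schedule: RegimeSchedule,
    mu0: float,
    seed: int | np.random.SeedSequence,
    participant_id: str = "regime",
    valence: str = "positive",
) -> tuple[LatentTrajectory, RatingSeries]:
    """Simulate with piecewise-constant volatility and noise levels.

    The scheduled levels replace the log random walks; the mean and the
    ratings are generated exactly as in :func:`simulate_subject`.
    """
    vmu, sd = schedule.levels()
    rng = np.random.default_rng(seed)
    mu, series = _walk_and_observe(
        mu0, vmu, sd, schedule.bounds, rng, participant_id, valence
    )
    return LatentTrajectory(mu=mu, vmu=vmu, sd=sd), series
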