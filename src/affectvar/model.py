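"""Grid-based Bayesian filter that inverts the generative model of affect.

The filter maintains a joint posterior over the five latent processes
``(mu, log vmu, log SD, kmu, vsd)`` on a dense 5-D grid and alternates, one
calendar day at a time, between

* a **predict** step, which pushes the posterior through the model dynamics
  (the mean diffuses with SD ``vmu``, the log-scales diffuse with their
  static rates, the rates stay put), and
* an **update** step, which reweights every grid cell by the Gaussian
  likelihood of the day's rating and renormalizes.

Days without a rating receive the predict step only — beliefs drift and
broaden, but no information is invented. The per-day posterior expectations
of ``vmu`` and ``SD`` are the filter's volatility and noise estimates: the
decomposition of observed affective variability into persistent and
transient change.

Grid filtering was chosen over particle filtering because it is
deterministic, admits an exact small-instance oracle, and is cheap at the
grid sizes daily diaries need. Transition kernels are row-normalized after
discretization so no probability leaks off the grid edges.

The statsmodels-style entry point is :class:`AffectFilter` (model) /
:class:`AffectFilterResults` (fit output); :func:`run_filter` and
:func:`run_filter_batch` are the functional engine underneath.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .exceptions import (
    ConfigurationError,
    ContractViolationError,
    DegenerateLikelihoodError,
    InsufficientDataError,
)
from .series import RatingSeries

_NORM_TOL = 1e-6  # input-normalization contract for predict/update
_MASS_TOL = 1e-10  # output-normalization guarantee


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class GridDim:
    """One discretized dimension of the joint state: support + prior mass."""

    points: np.ndarray
    prior: np.ndarray

    @classmethod
    def linear(cls, lo: float, hi: float, n: int) -> "GridDim":
        pts = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2.0])
        return cls(points=pts, prior=np.full(len(pts), 1.0 / len(pts)))

    @classmethod
    def log_spaced(cls, lo: float, hi: float, n: int) -> "GridDim":
        pts = np.geomspace(lo, hi, n) if n > 1 else np.array([math.sqrt(lo * hi)])
        return cls(points=pts, prior=np.full(len(pts), 1.0 / len(pts)))

    @classmethod
    def pinned(cls, value: float) -> "GridDim":
        return cls(points=np.array([value]), prior=np.array([1.0]))

    def validate(self, name: str) -> None:
        pts = np.asarray(self.points, dtype=float)
        pri = np.asarray(self.prior, dtype=float)
        if pts.size == 0:
            raise ConfigurationError(f"grid dimension {name!r} is empty")
        if not np.all(np.isfinite(pts)):
            raise ConfigurationError(f"grid dimension {name!r} has non-finite points")
        if pts.size > 1 and np.any(np.diff(pts) <= 0):
            raise ConfigurationError(f"grid dimension {name!r} must be strictly increasing")
        if pri.shape != pts.shape or np.any(pri < 0) or abs(pri.sum() - 1.0) > _NORM_TOL:
            raise ConfigurationError(f"prior on {name!r} must be a probability vector")


@dataclass(frozen=True)
class FilterConfig:
    """Grid specification and priors for the five state dimensions.

    ``mu`` is gridded in rating units; volatility and noise are gridded on
    their logarithms (matching the log-random-walk dynamics); the static
    rates ``kmu`` and ``vsd`` are gridded on their natural scale.
    ``missing_policy`` is fixed to ``"predict_only"``: unrated days advance
    the dynamics by exactly one predict step, with no interpolation.
    """

    mu: GridDim
    log_vmu: GridDim
    log_sd: GridDim
    kmu: GridDim
    vsd: GridDim
    missing_policy: str = "predict_only"

    def __post_init__(self) -> None:
        for name in ("mu", "log_vmu", "log_sd", "kmu", "vsd"):
            getattr(self, name).validate(name)
        if self.missing_policy != "predict_only":
            raise ConfigurationError("missing_policy must be 'predict_only'")

    @classmethod
    def default(
        cls,
        bounds: tuple[float, float] = (0.0, 1.0),
        n_mu: int = 25,
        n_log_vmu: int = 15,
        n_log_sd: int = 15,
        n_kmu: int = 7,
        n_vsd: int = 7,
    ) -> "FilterConfig":
        """Default grid for a rating scale ``[lo, hi]``.

        The mu grid spans the bounds padded by 10% of the scale range; the
        log-volatility and log-noise grids span 0.001–0.5 scale ranges (a
        scale-free band wide enough for daily affect dynamics); the static
        rates span 0.01–0.5 per day. All priors are uniform over the grid.
        """
        lo, hi = bounds
        if not lo < hi:
            raise ConfigurationError(f"bounds must satisfy lo < hi, got {bounds}")
        r = hi - lo
        return cls(
            mu=GridDim.linear(lo - 0.1 * r, hi + 0.1 * r, n_mu),
            log_vmu=GridDim.linear(math.log(0.001 * r), math.log(0.5 * r), n_log_vmu),
            log_sd=GridDim.linear(math.log(0.001 * r), math.log(0.5 * r), n_log_sd),
            kmu=GridDim.log_spaced(0.01, 0.5, n_kmu),
            vsd=GridDim.log_spaced(0.01, 0.5, n_vsd),
        )

    @property
    def shape(self) -> tuple[int, int, int, int, int]:
        return (
            len(self.mu.points),
            len(self.log_vmu.points),
            len(self.log_sd.points),
            len(self.kmu.points),
            len(self.vsd.points),
        )


# ---------------------------------------------------------------------------
# transition kernels
# ---------------------------------------------------------------------------
def _gaussian_kernel(points: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Row-normalized Gaussian transition kernels on a fixed grid.

    Returns ``K[c, j, i] = P(point_i at t | point_j at t-1, sd = sds[c])``.
    Rows are normalized after discretization so mass is conserved at the
    grid edges; an SD far below the grid spacing degenerates gracefully to
    the identity (stay-put) kernel.
    """
    d2 = (points[None, :] - points[:, None]) ** 2  # (j, i)
    with np.errstate(divide="ignore", over="ignore"):
        k = np.exp(-d2[None, :, :] / (2.0 * np.maximum(sds, 1e-300)[:, None, None] ** 2))
    k /= k.sum(axis=2, keepdims=True)
    return k


class _Kernels:
    """Pre-computed transition kernels and expectation vectors for a config."""

    def __init__(self, config: FilterConfig):
        self.config = config
        vmu_vals = np.exp(config.log_vmu.points)
        self.t_mu = _gaussian_kernel(config.mu.points, vmu_vals)  # (v, j, i)
        self.t_lv = _gaussian_kernel(config.log_vmu.points, config.kmu.points)  # (k, u, v)
        self.t_ls = _gaussian_kernel(config.log_sd.points, config.vsd.points)  # (w, r, s)
        self.mu_pts = config.mu.points
        self.vmu_pts = vmu_vals
        self.sd_pts = np.exp(config.log_sd.points)
        self.kmu_pts = config.kmu.points
        self.vsd_pts = config.vsd.points
        # cell edges of the mu grid, for the cell-integrated likelihood
        pts = self.mu_pts
        if len(pts) > 1:
            self.mu_edges = np.concatenate(
                [
                    [pts[0] - (pts[1] - pts[0]) / 2.0],
                    (pts[:-1] + pts[1:]) / 2.0,
                    [pts[-1] + (pts[-1] - pts[-2]) / 2.0],
                ]
            )
        else:
            self.mu_edges = np.array([-np.inf, np.inf])

    def predict(self, p: np.ndarray) -> np.ndarray:
        """One predict step on a batch ``p`` of shape (B, mu, lv, ls, k, w).

        The mean diffuses conditional on the *pre-step* volatility, so the
        mu convolution is applied before the log-volatility convolution.
        Each convolution is batched over its conditioning dimension and
        dispatched to BLAS as a stack of matrix products. Row-normalized
        kernels conserve total mass, so no renormalization is needed; a
        final division guards against accumulated roundoff.
        """
        b = p.shape[0]
        nm, nv, ns, nk, nw = self.config.shape
        # mu | vmu_{t-1}: (v, i, j) @ (v, j, .)
        q = np.ascontiguousarray(p.transpose(2, 1, 0, 3, 4, 5)).reshape(nv, nm, -1)
        q = np.matmul(self.t_mu.transpose(0, 2, 1), q)
        p = q.reshape(nv, nm, b, ns, nk, nw).transpose(2, 1, 0, 3, 4, 5)
        # log_vmu | kmu: (k, v, u) @ (k, u, .)
        q = np.ascontiguousarray(p.transpose(4, 2, 0, 1, 3, 5)).reshape(nk, nv, -1)
        q = np.matmul(self.t_lv.transpose(0, 2, 1), q)
        p = q.reshape(nk, nv, b, nm, ns, nw).transpose(2, 3, 1, 4, 0, 5)
        # log_sd | vsd: (w, s, r) @ (w, r, .)
        q = np.ascontiguousarray(p.transpose(5, 3, 0, 1, 2, 4)).reshape(nw, ns, -1)
        q = np.matmul(self.t_ls.transpose(0, 2, 1), q)
        p = np.ascontiguousarray(q.reshape(nw, ns, b, nm, nv, nk).transpose(2, 3, 4, 1, 5, 0))
        return p / p.sum(axis=(1, 2, 3, 4, 5), keepdims=True)

    def likelihood(self, y: np.ndarray) -> np.ndarray:
        """Observation likelihood over the (mu, log_sd) plane, per batch row.

        Each mu cell is scored by the Gaussian probability *mass* that falls
        inside the cell, ``Phi((upper-y)/SD) - Phi((lower-y)/SD)``, rather
        than the density at the cell midpoint. The two agree when SD is
        large against the grid spacing, but the integrated form remains
        exact when SD is small, where the midpoint rule aliases observation
        noise into spurious mean movement. NaN entries (missing days) yield
        a flat likelihood of one, i.e. no update.
        """
        yy = y[:, None, None]
        z_hi = (self.mu_edges[1:][None, :, None] - yy) / self.sd_pts[None, None, :]
        z_lo = (self.mu_edges[:-1][None, :, None] - yy) / self.sd_pts[None, None, :]
        l = ndtr(z_hi) - ndtr(z_lo)  # may underflow to exact 0 far from y
        return np.where(np.isnan(yy), 1.0, l)

    def expectations(self, p: np.ndarray) -> dict[str, np.ndarray]:
        """Posterior means of mu, vmu, SD, kmu and vsd for each batch row."""
        return {
            "mu": p.sum(axis=(2, 3, 4, 5)) @ self.mu_pts,
            "vmu": p.sum(axis=(1, 3, 4, 5)) @ self.vmu_pts,
            "sd": p.sum(axis=(1, 2, 4, 5)) @ self.sd_pts,
            "kmu": p.sum(axis=(1, 2, 3, 5)) @ self.kmu_pts,
            "vsd": p.sum(axis=(1, 2, 3, 4)) @ self.vsd_pts,
        }


class _BatchEngine:
    """Buffer-reusing forward pass over a fixed-size batch of series.

    Numerically identical to composing :func:`predict_step` and
    :func:`update_step` day by day, but laid out for speed: the joint is
    held as ``(kmu, vsd, batch, log_sd, log_vmu, mu)`` with mu contiguous,
    so every convolution becomes one large BLAS matrix product and every
    transposition moves whole mu-rows. Buffers are allocated once, and
    normalization is deferred to one division per day (row-normalized
    kernels conserve mass; only the likelihood changes it).
    """

    def __init__(self, kern: _Kernels, batch: int):
        self.kern = kern
        self.b = batch
        nm, nv, ns, nk, nw = kern.config.shape
        self.dims = (nm, nv, ns, nk, nw)
        self.shape = (nk, nw, batch, ns, nv, nm)  # engine layout
        self.p = np.empty(self.shape)
        self._wa = np.empty(self.shape)  # work buffers, reinterpreted per stage
        self._wb = np.empty(self.shape)
        self._wc = np.empty(self.shape)
        self._tm = kern.t_mu  # (v, j, i)
        self._tv = np.ascontiguousarray(kern.t_lv.transpose(0, 2, 1))  # (k, v, u)
        self._ts = np.ascontiguousarray(kern.t_ls.transpose(0, 2, 1))  # (w, s, r)

    def reset(self, prior: np.ndarray) -> None:
        # prior arrives in (mu, lv, ls, k, w) order
        self.p[:] = prior.transpose(3, 4, 2, 1, 0)[:, :, None]

    def predict(self) -> None:
        nm, nv, ns, nk, nw = self.dims
        b = self.b
        # mu | vmu_{t-1}: gather v first, then one GEMM per v
        q1 = self._wa.reshape(nv, nk, nw, b, ns, nm)
        np.copyto(q1, self.p.transpose(4, 0, 1, 2, 3, 5))
        o1 = self._wb.reshape(nv, nk * nw * b * ns, nm)
        for v in range(nv):
            np.matmul(q1[v].reshape(-1, nm), self._tm[v], out=o1[v])
        # log_vmu | kmu: bring k first (leading-axis swap), one GEMM per k
        q2 = self._wc.reshape(nk, nv, nw * b * ns * nm)
        np.copyto(
            q2,
            self._wb.reshape(nv, nk, nw * b * ns * nm).transpose(1, 0, 2),
        )
        o2 = self._wa.reshape(nk, nv, nw * b * ns * nm)
        np.matmul(self._tv, q2, out=o2)
        # log_sd | vsd: gather (w, s) first, one GEMM per w
        q3 = self._wb.reshape(nw, ns, nk, nv, b, nm)
        np.copyto(
            q3,
            self._wa.reshape(nk, nv, nw, b, ns, nm).transpose(2, 4, 0, 1, 3, 5),
        )
        o3 = self._wc.reshape(nw, ns, nk * nv * b * nm)
        np.matmul(self._ts, q3.reshape(nw, ns, -1), out=o3)
        # back to engine layout (k, w, b, s, v, i)
        np.copyto(
            self.p,
            self._wc.reshape(nw, ns, nk, nv, b, nm).transpose(2, 0, 4, 1, 3, 5),
        )

    def mu_marginal(self) -> np.ndarray:
        nm = self.dims[0]
        # sum leading (k, w) blocks first (contiguous adds), then (s, v)
        a = self.p.reshape(-1, self.b, self.dims[2], self.dims[1], nm).sum(axis=0)
        return a.sum(axis=(1, 2))

    def update(self, y: np.ndarray) -> np.ndarray:
        """Multiply in the day's likelihood; return the (unnormalized) mass."""
        l = self.kern.likelihood(y)  # (b, i, s)
        self.p *= l.transpose(0, 2, 1)[None, None, :, :, None, :]
        mass = self.p.reshape(-1, self.b, self.dims[2] * self.dims[1] * self.dims[0]).sum(
            axis=(0, 2)
        )
        return mass

    def normalize(self, mass: np.ndarray) -> None:
        self.p /= mass[None, None, :, None, None, None]
        # Flush vanishing cells to exact zero: the posterior concentrates and
        # leaves most of the grid holding subnormal-range mass, which slows
        # BLAS by orders of magnitude and contributes nothing (< 1e-250 total
        # across the whole grid) to any expectation.
        np.copyto(self.p, 0.0, where=self.p < 1e-280)

    def scale_expectations(self) -> dict[str, np.ndarray]:
        """Means of vmu, SD, kmu, vsd from one partial reduction over mu."""
        a = self.p.sum(axis=5)  # (k, w, b, s, v)
        k = self.kern
        return {
            "vmu": a.sum(axis=(0, 1, 3)) @ k.vmu_pts,
            "sd": a.sum(axis=(0, 1, 4)) @ k.sd_pts,
            "kmu": a.sum(axis=(1, 3, 4)).T @ k.kmu_pts,
            "vsd": a.sum(axis=(0, 3, 4)).T @ k.vsd_pts,
        }


# ---------------------------------------------------------------------------
# posterior object + single-step operations
# ---------------------------------------------------------------------------
@dataclass
class FilterPosterior:
    """The filter's belief: a joint probability mass over the 5-D grid."""

    joint: np.ndarray
    config: FilterConfig
    t: int = 0  # index of the last assimilated observation (0 = prior)

    def __post_init__(self) -> None:
        if self.joint.shape != self.config.shape:
            raise ConfigurationError(
                f"joint shape {self.joint.shape} does not match grid {self.config.shape}"
            )

    @property
    def total_mass(self) -> float:
        return float(self.joint.sum())

    def marginal(self, dim: str) -> np.ndarray:
        axes = {"mu": 0, "log_vmu": 1, "log_sd": 2, "kmu": 3, "vsd": 4}
        keep = axes[dim]
        return self.joint.sum(axis=tuple(a for a in range(5) if a != keep))

    def mean(self, dim: str) -> float:
        m = self.marginal(dim)
        pts = {
            "mu": self.config.mu.points,
            "log_vmu": np.exp(self.config.log_vmu.points),
            "log_sd": np.exp(self.config.log_sd.points),
            "kmu": self.config.kmu.points,
            "vsd": self.config.vsd.points,
        }[dim]
        return float(m @ pts)


def init_posterior(config: FilterConfig) -> FilterPosterior:
    """Joint prior = outer product of the per-dimension priors, normalized."""
    joint = (
        config.mu.prior[:, None, None, None, None]
        * config.log_vmu.prior[None, :, None, None, None]
        * config.log_sd.prior[None, None, :, None, None]
        * config.kmu.prior[None, None, None, :, None]
        * config.vsd.prior[None, None, None, None, :]
    )
    joint = joint / joint.sum()
    return FilterPosterior(joint=joint, config=config)


def _check_normalized(post: FilterPosterior) -> None:
    if abs(post.total_mass - 1.0) > _NORM_TOL:
        raise ContractViolationError(
            f"posterior mass {post.total_mass} is not normalized"
        )


def predict_step(post: FilterPosterior, config: FilterConfig | None = None) -> FilterPosterior:
    """Push the posterior through one day of the model dynamics."""
    config = config or post.config
    _check_normalized(post)
    kern = _Kernels(config)
    p = kern.predict(post.joint[None])[0]
    return FilterPosterior(joint=p, config=config, t=post.t)


def update_step(post: FilterPosterior, y: float) -> FilterPosterior:
    """Assimilate one rating by Gaussian-likelihood reweighting."""
    _check_normalized(post)
    config = post.config
    mu_lo, mu_hi = config.mu.points[0], config.mu.points[-1]
    if y < mu_lo or y > mu_hi:
        warnings.warn(
            f"rating {y} outside the mu grid [{mu_lo}, {mu_hi}]; clamping",
            stacklevel=2,
        )
        y = min(max(y, mu_lo), mu_hi)
    kern = _Kernels(config)
    l = kern.likelihood(np.array([y]))[0]  # (mu, ls)
    p = post.joint * l[:, None, :, None, None]
    mass = p.sum()
    if not mass > 0:
        raise DegenerateLikelihoodError(
            "posterior mass underflowed to zero during update; "
            "widen the mu or log-SD grid ranges"
        )
    return FilterPosterior(joint=p / mass, config=config, t=post.t + 1)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------
@dataclass
class FilterTrajectory:
    """Per-day posterior expectations produced by a filter run."""

    days: np.ndarray
    predicted_mean: np.ndarray
    posterior_mean: np.ndarray
    volatility: np.ndarray
    noise: np.ndarray
    e_kmu: np.ndarray
    e_vsd: np.ndarray
    observed: np.ndarray
    participant_id: str = "sim"
    valence: str = "positive"

    def __post_init__(self) -> None:
        if np.any(self.volatility <= 0) or np.any(self.noise <= 0):
            raise ContractViolationError("volatility and noise estimates must stay positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "valence": self.valence,
                "day": self.days,
                "predicted_mean": self.predicted_mean,
                "posterior_mean": self.posterior_mean,
                "volatility": self.volatility,
                "noise": self.noise,
                "e_kmu": self.e_kmu,
                "e_vsd": self.e_vsd,
                "observed": self.observed,
            }
        )

    def at_day(self, day: int) -> dict[str, float]:
        i = int(np.searchsorted(self.days, day))
        if i >= len(self.days) or self.days[i] != day:
            raise KeyError(f"day {day} not in trajectory")
        return {
            "predicted_mean": float(self.predicted_mean[i]),
            "posterior_mean": float(self.posterior_mean[i]),
            "volatility": float(self.volatility[i]),
            "noise": float(self.noise[i]),
            "e_kmu": float(self.e_kmu[i]),
            "e_vsd": float(self.e_vsd[i]),
        }


def run_filter_batch(
    series: Sequence[RatingSeries],
    config: FilterConfig | None = None,
    chunk_size: int | None = None,
) -> list[FilterTrajectory]:
    """Run the filter over many series sharing one grid configuration.

    Series are stacked in cache-sized chunks and stepped jointly, which
    turns the per-day convolutions into stacks of matrix products; results
    are identical to filtering each series alone. Series may differ in
    length and missingness. Deterministic.
    """
    if not series:
        return []
    if config is None:
        config = FilterConfig.default(series[0].bounds)
    full = [s.reindex_full() for s in series]
    if min(len(s) for s in full) < 2:
        raise InsufficientDataError("each series must span at least 2 days")
    mu_lo, mu_hi = config.mu.points[0], config.mu.points[-1]
    for s in full:
        obs = s.values[~np.isnan(s.values)]
        if np.any(obs < mu_lo) or np.any(obs > mu_hi):
            warnings.warn(
                f"series {s.participant_id}/{s.valence} has ratings outside the "
                f"mu grid [{mu_lo}, {mu_hi}]; clamping",
                stacklevel=2,
            )

    kern = _Kernels(config)
    prior = init_posterior(config).joint
    cells = int(np.prod(config.shape))
    if chunk_size is None:
        # keep the working set near L2/L3 size; allocation reuse does the rest
        chunk_size = int(np.clip(6_000_000 // (cells * 8), 1, 64))

    out: list[FilterTrajectory] = []
    for start in range(0, len(full), chunk_size):
        chunk = full[start : start + chunk_size]
        b = len(chunk)
        t_max = max(len(s) for s in chunk)
        y = np.full((b, t_max), np.nan)
        for i, s in enumerate(chunk):
            y[i, : len(s)] = np.clip(s.values, mu_lo, mu_hi)

        engine = _BatchEngine(kern, b)
        engine.reset(prior)
        rec = {
            k: np.empty((b, t_max))
            for k in ("predicted_mean", "posterior_mean", "volatility", "noise", "e_kmu", "e_vsd")
        }
        for t in range(t_max):
            engine.predict()
            rec["predicted_mean"][:, t] = engine.mu_marginal() @ kern.mu_pts
            mass = engine.update(y[:, t])
            if np.any(mass <= 0):
                bad = [chunk[i].participant_id for i in np.where(mass <= 0)[0]]
                raise DegenerateLikelihoodError(
                    f"posterior mass underflowed for series {bad}; widen the grid"
                )
            engine.normalize(mass)
            rec["posterior_mean"][:, t] = engine.mu_marginal() @ kern.mu_pts
            e = engine.scale_expectations()
            rec["volatility"][:, t] = e["vmu"]
            rec["noise"][:, t] = e["sd"]
            rec["e_kmu"][:, t] = e["kmu"]
            rec["e_vsd"][:, t] = e["vsd"]

        for i, s in enumerate(chunk):
            n = len(s)
            out.append(
                FilterTrajectory(
                    days=s.days,
                    predicted_mean=rec["predicted_mean"][i, :n],
                    posterior_mean=rec["posterior_mean"][i, :n],
                    volatility=rec["volatility"][i, :n],
                    noise=rec["noise"][i, :n],
                    e_kmu=rec["e_kmu"][i, :n],
                    e_vsd=rec["e_vsd"][i, :n],
                    observed=~np.isnan(s.values),
                    participant_id=s.participant_id,
                    valence=s.valence,
                )
            )
    return out


def run_filter(series: RatingSeries, config: FilterConfig | None = None) -> FilterTrajectory:
    """Run the filter over one rating series (one step per calendar day)."""
    return run_filter_batch([series], config)[0]


def kalman_reference(
    series: RatingSeries,
    vmu_fixed: float,
    sd_fixed: float,
) -> np.ndarray:
    """Closed-form local-level posterior means of mu (fixed-scales limit).

    With volatility and noise known and constant the generative model is the
    local-level model, whose filtered mean has the standard linear-Gaussian
    recursion. Serves as an independent check of the grid filter with the
    scale dimensions pinned. Requires a complete (no-missing) series.
    """
    if not (vmu_fixed > 0 and sd_fixed > 0):
        raise ContractViolationError("vmu_fixed and sd_fixed must be > 0")
    if np.any(np.isnan(series.reindex_full().values)):
        raise ContractViolationError("kalman_reference requires a complete series")
    y = series.values
    q, r = vmu_fixed**2, sd_fixed**2
    m, v = 0.0, 1e12  # diffuse prior: first update lands on y_1
    means = np.empty(len(y))
    for t, yt in enumerate(y):
        v = v + q
        k = v / (v + r)
        m = m + k * (yt - m)
        v = (1.0 - k) * v
        means[t] = m
    return means


# ---------------------------------------------------------------------------
# statsmodels-style surface
# ---------------------------------------------------------------------------
class AffectFilter:
    """Model object: a rating series plus a grid configuration.

    Examples
    --------
    >>> traj, series = simulate_subject(GenerativeParams(0.5, 0.03, 0.08, n_steps=50), 1)
    >>> res = AffectFilter(series).fit()
    >>> res.volatility[-1], res.noise[-1]  # day-50 decomposition
    """

    def __init__(self, series: RatingSeries, config: FilterConfig | None = None):
        self.series = series
        self.config = config or FilterConfig.default(series.bounds)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        participant_id: str,
        valence: str,
        bounds: tuple[float, float] = (0.0, 1.0),
        config: FilterConfig | None = None,
    ) -> "AffectFilter":
        """Build from a long-format frame (participant_id, valence, day, value)."""
        sub = data[(data["participant_id"] == participant_id) & (data["valence"] == valence)]
        if sub.empty:
            raise InsufficientDataError(
                f"no rows for participant {participant_id!r} / valence {valence!r}"
            )
        s = RatingSeries(
            participant_id=participant_id,
            valence=valence,
            days=sub["day"].to_numpy(),
            values=sub["value"].to_numpy(dtype=float),
            bounds=bounds,
        )
        return cls(s, config=config)

    def fit(self) -> "AffectFilterResults":
        trajectory = run_filter(self.series, self.config)
        return AffectFilterResults(self, trajectory)


class AffectFilterResults:
    """Fit output: per-day posterior expectations plus convenience views."""

    def __init__(self, model: AffectFilter, trajectory: FilterTrajectory):
        self.model = model
        self.trajectory = trajectory

    # array views -----------------------------------------------------------
    @property
    def days(self) -> np.ndarray:
        return self.trajectory.days

    @property
    def predicted_mean(self) -> np.ndarray:
        return self.trajectory.predicted_mean

    @property
    def posterior_mean(self) -> np.ndarray:
        return self.trajectory.posterior_mean

    @property
    def volatility(self) -> np.ndarray:
        return self.trajectory.volatility

    @property
    def noise(self) -> np.ndarray:
        return self.trajectory.noise

    def to_frame(self) -> pd.DataFrame:
        return self.trajectory.to_frame()

    def endpoint(self, day: int | None = None) -> dict[str, float]:
        """Posterior expectations at a study day (default: last day)."""
        if day is None:
            day = int(self.trajectory.days[-1])
        return self.trajectory.at_day(day)

    def summary(self) -> str:
        s = self.model.series
        end = self.endpoint()
        n_obs = s.n_observed
        lines = [
            "Affect volatility/noise decomposition (grid Bayesian filter)",
            "=" * 62,
            f"participant: {s.participant_id:<20} valence: {s.valence}",
            f"days: {int(self.days[0])}..{int(self.days[-1])}   observed: {n_obs}   "
            f"missing: {len(self.days) - n_obs}",
            f"grid: mu={len(self.model.config.mu.points)} x "
            f"log_vmu={len(self.model.config.log_vmu.points)} x "
            f"log_sd={len(self.model.config.log_sd.points)} x "
            f"kmu={len(self.model.config.kmu.points)} x "
            f"vsd={len(self.model.config.vsd.points)}",
            "-" * 62,
            f"final posterior mean of affect   E[mu]   = {end['posterior_mean']:.4f}",
            f"final volatility (persistent)    E[vmu]  = {end['volatility']:.4f}",
            f"final noise (transient)          E[SD]   = {end['noise']:.4f}",
            f"final rate of volatility change  E[kmu]  = {end['e_kmu']:.4f}",
            f"final rate of noise change       E[vsd]  = {end['e_vsd']:.4f}",
            "=" * 62,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Two-panel figure: ratings + tracked mean; volatility and noise."""
        import matplotlib.pyplot as plt

        if ax is None:
            fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 6))
        else:
            axes = ax
            fig = axes[0].figure
        t = self.trajectory
        s = self.model.series.reindex_full()
        axes[0].plot(s.days, s.values, "k.-", lw=0.7, ms=3, label="ratings")
        axes[0].plot(t.days, t.predicted_mean, color="tab:green", label="predicted mean")
        axes[0].set_ylabel("affect rating")
        axes[0].legend(loc="best", fontsize=8)
        axes[1].plot(t.days, t.volatility, color="tab:red", label="volatility E[vmu]")
        axes[1].plot(t.days, t.noise, color="tab:blue", label="noise E[SD]")
        axes[1].set_xlabel("study day")
        axes[1].set_ylabel("scale (rating units)")
        axes[1].legend(loc="best", fontsize=8)
        return fig
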