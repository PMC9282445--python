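"""From raw diaries to group and treatment inferences.

The workflow mirrors how filter-derived variability endpoints are analyzed
in mood-diary studies:

1. composite positive/negative scores per participant;
2. inclusion: at least 10 observed composite ratings;
3. windowing: the contiguous 50-day stretch with the fewest missing days;
4. the Bayesian filter on the (0-1 normalized) window, yielding
   volatility and noise at the window's final (50th) day;
5. Box-Cox transform (lambda = 0.2) of the skewed filter endpoints;
6. mixed-design repeated-measures ANOVA with within-subject factors
   *cause of variability* (volatility, noise) and *valence* (positive,
   negative), a between-subject factor (group or treatment arm), optional
   covariates, and Bonferroni-corrected (x3) pairwise group contrasts;
7. for the trial, change scores (end of treatment minus end of run-in)
   analyzed untransformed, plus per-endpoint two-sample t tests.

Repeated-measures F tests are computed by the orthogonal-contrast
decomposition (each within-effect is a per-subject contrast score analyzed
by a between-subject linear model), which for two-level within factors is
exactly the classical univariate mixed-design ANOVA.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .cohort import CohortDataset, TrialDataset, dataset_composites
from .exceptions import (
    ContractViolationError,
    DesignError,
    DomainError,
    PipelineError,
)
from .metrics import summary_moments
from .model import FilterConfig, run_filter_batch
from .series import RatingSeries

logger = logging.getLogger(__name__)

def pipeline_filter_config(bounds: tuple[float, float] = (0.0, 1.0)) -> FilterConfig:
    """Filter grid used for cohort/trial endpoint estimation.

    Slightly coarser than the single-series default (endpoint expectations
    are insensitive to grid resolution, and a whole cohort is filtered), and
    with the static-rate supports capped at 0.2/day instead of 0.5/day: a
    rate of 0.5 lets volatility swing by a factor of ~1.6 per day, far
    faster than mood dynamics over 40-60-day diaries, and only injects
    day-to-day jitter into the endpoint estimates.
    """
    from .model import GridDim

    base = FilterConfig.default(bounds, n_mu=21, n_log_vmu=13, n_log_sd=13)
    return FilterConfig(
        mu=base.mu,
        log_vmu=base.log_vmu,
        log_sd=base.log_sd,
        kmu=GridDim.log_spaced(0.01, 0.2, 5),
        vsd=GridDim.log_spaced(0.01, 0.2, 5),
    )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------
def select_window(series: RatingSeries, width: int = 50) -> RatingSeries:
    """The contiguous ``width``-day window with the fewest missing days.

    Ties are broken by the earliest start. A series spanning fewer than
    ``width`` calendar days is returned whole with a warning.
    """
    full = series.reindex_full()
    span = len(full)
    if span < width:
        warnings.warn(
            f"series {series.participant_id}/{series.valence} spans {span} < "
            f"{width} days; using it whole",
            stacklevel=2,
        )
        return full
    miss = np.isnan(full.values).astype(int)
    cum = np.concatenate([[0], np.cumsum(miss)])
    counts = cum[width:] - cum[:-width]  # missing per window start
    start = int(np.argmin(counts))
    return full.window(int(full.days[start]), int(full.days[start]) + width - 1)


def apply_inclusion(dataset: CohortDataset, min_ratings: int = 10) -> CohortDataset:
    """Drop participants with fewer than ``min_ratings`` observed composites.

    A participant is removed if *either* valence has too few observed
    composite ratings; removals are logged.
    """
    composites = dataset_composites(dataset.items, dataset.instrument)
    keep, dropped = [], []
    for pid, pair in composites.items():
        if all(s.n_observed >= min_ratings for s in pair.values()):
            keep.append(pid)
        else:
            dropped.append(pid)
    for pid in dropped:
        logger.info("excluding participant %s: fewer than %d ratings", pid, min_ratings)
    if not keep:
        raise PipelineError("no participants left after the inclusion criterion")
    return CohortDataset(
        items=dataset.items[dataset.items["participant_id"].isin(keep)].reset_index(drop=True),
        participants=dataset.participants[
            dataset.participants["participant_id"].isin(keep)
        ].reset_index(drop=True),
        truth=dataset.truth[dataset.truth["participant_id"].isin(keep)].reset_index(drop=True),
        instrument=dataset.instrument,
    )


def boxcox_transform(x, lam: float = 0.2):
    """Box-Cox power transform, ``(x**lam - 1) / lam`` (log for lam = 0)."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("boxcox_transform requires strictly positive input")
    if lam == 0.0:
        out = np.log(arr)
    else:
        out = (arr**lam - 1.0) / lam
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def bonferroni(p: float, k: int = 3) -> float:
    """Bonferroni-adjusted p value: ``min(1, k * p)``."""
    return min(1.0, k * p)


@dataclass
class AnovaResult:
    """One inferential effect: an F (or squared-t) test with its p value."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    p_bonf: float | None = None
    statistic: float | None = None  # signed t, where the test is a t test
    estimate: float | None = None  # group/arm difference on the DV scale

    def __post_init__(self) -> None:
        if self.F < -1e-12 or not 0.0 <= self.p <= 1.0:
            raise ContractViolationError(f"invalid test result for {self.effect}")

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "F": self.F,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p": self.p,
            "p_bonf": self.p_bonf,
            "statistic": self.statistic,
            "estimate": self.estimate,
        }


def results_frame(results: Sequence[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


# ---------------------------------------------------------------------------
# endpoint construction
# ---------------------------------------------------------------------------
def build_cohort_endpoints(
    dataset: CohortDataset,
    filter_config: FilterConfig | None = None,
    window_width: int = 50,
    min_ratings: int = 10,
) -> pd.DataFrame:
    """One row per participant x valence with day-50 filter endpoints.

    Composites are normalized to the latent 0-1 scale before filtering, so
    mean, SD, volatility and noise all share those units. The volatility
    and noise endpoints are the posterior expectations on the final (50th)
    day of each participant's best window.
    """
    dataset = apply_inclusion(dataset, min_ratings=min_ratings)
    composites = dataset_composites(dataset.items, dataset.instrument)
    series, meta = [], []
    for pid, pair in composites.items():
        for valence in ("positive", "negative"):
            s = select_window(pair[valence].normalized(), width=window_width)
            series.append(s)
            meta.append((pid, valence))
    if filter_config is None:
        filter_config = pipeline_filter_config((0.0, 1.0))
    trajectories = run_filter_batch(series, filter_config)
    parts = dataset.participants.set_index("participant_id")
    rows = []
    for (pid, valence), s, traj in zip(meta, series, trajectories):
        mean, sd = summary_moments(s)
        info = parts.loc[pid]
        rows.append(
            {
                "participant_id": pid,
                "group": info["group"],
                "lithium": bool(info["lithium"]),
                "age": float(info["age"]),
                "sex": info["sex"],
                "education": int(info["education"]),
                "valence": valence,
                "mean": mean,
                "sd": sd,
                "volatility": float(traj.volatility[-1]),
                "noise": float(traj.noise[-1]),
            }
        )
    return pd.DataFrame(rows)


def build_trial_endpoints(
    trial: TrialDataset,
    filter_config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Run-in-end and end-of-treatment filter estimates plus change scores.

    The filter runs over the whole diary (run-in + treatment). "End of
    run-in" is the estimate on the last run-in day; "end of treatment" is
    the estimate on the final treatment day; changes are their differences.
    Participants whose diary does not span the full schedule, or who did
    not rate on an endpoint day (so that the endpoint estimate would be
    prediction-only), are excluded with a log message.
    """
    if filter_config is None:
        filter_config = pipeline_filter_config((0.0, 1.0))
    end_day = trial.run_in_days + trial.treatment_days
    composites = dataset_composites(trial.items, trial.instrument)
    series, meta = [], []
    for pid, pair in composites.items():
        spans = [
            (int(s.days[0]), int(s.days[-1])) for s in pair.values()
        ]
        if any(d0 > 1 or d1 < end_day for d0, d1 in spans):
            logger.info("excluding trial participant %s: diary does not span the schedule", pid)
            continue
        full = {v: s.reindex_full() for v, s in pair.items()}
        if any(
            np.isnan(s.values[day - 1])
            for s in full.values()
            for day in (trial.run_in_days, end_day)
        ):
            logger.info(
                "excluding trial participant %s: no rating on an endpoint day", pid
            )
            continue
        for valence in ("positive", "negative"):
            series.append(pair[valence].normalized())
            meta.append((pid, valence))
    if not series:
        raise PipelineError("no trial participants with complete schedules")
    trajectories = run_filter_batch(series, filter_config)
    parts = trial.participants.set_index("participant_id")
    rows = []
    for (pid, valence), s, traj in zip(meta, series, trajectories):
        at_runin = traj.at_day(trial.run_in_days)
        at_end = traj.at_day(end_day)
        mean, sd = summary_moments(s)
        rows.append(
            {
                "participant_id": pid,
                "arm": parts.loc[pid, "arm"],
                "valence": valence,
                "mean": mean,
                "sd": sd,
                "runin_volatility": at_runin["volatility"],
                "runin_noise": at_runin["noise"],
                "post_volatility": at_end["volatility"],
                "post_noise": at_end["noise"],
                "change_volatility": at_end["volatility"] - at_runin["volatility"],
                "change_noise": at_end["noise"] - at_runin["noise"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated-measures machinery (orthogonal-contrast decomposition)
# ---------------------------------------------------------------------------
def _wide_cells(endpoints: pd.DataFrame, value_cols: tuple[str, str]) -> pd.DataFrame:
    """Pivot participant x valence rows into the four within-cells."""
    vol, noi = value_cols
    wide = endpoints.pivot_table(
        index="participant_id", columns="valence", values=[vol, noi], aggfunc="first"
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    needed = [f"{vol}_positive", f"{vol}_negative", f"{noi}_positive", f"{noi}_negative"]
    missing = [c for c in needed if c not in wide.columns]
    if missing:
        raise DesignError(f"endpoint table lacks cells {missing}")
    return wide[needed]


def _between_info(endpoints: pd.DataFrame, factor: str, covariates: Sequence[str]) -> pd.DataFrame:
    cols = ["participant_id", factor, *covariates]
    info = endpoints[cols].drop_duplicates("participant_id").set_index("participant_id")
    if "sex" in covariates:
        info = info.assign(sex=(info["sex"] == "female").astype(float))
    return info


def _usable_covariates(info: pd.DataFrame, covariates: Sequence[str]) -> tuple[str, ...]:
    """Drop covariates that are constant in the analyzed rows (e.g. sex
    after subsetting to one sex); a constant regressor is inestimable."""
    kept = tuple(c for c in covariates if info[c].nunique() > 1)
    for c in set(covariates) - set(kept):
        logger.info("dropping constant covariate %r", c)
    return kept


def _contrast_tests(
    scores: pd.Series,
    info: pd.DataFrame,
    factor: str,
    covariates: Sequence[str],
    effect_between: str,
    effect_within: str | None,
) -> list[AnovaResult]:
    """F tests for one within-contrast: its mean (within main effect) and
    its interaction with the between factor, via an OLS on the contrast."""
    data = info.join(scores.rename("score")).dropna()
    for c in covariates:  # center covariates so the intercept is the grand mean effect
        data[c] = data[c] - data[c].mean()
    # sum (effects) coding: the intercept is the unweighted grand mean across
    # factor levels, which is what the within-subject main-effect test needs
    factor_term = f"C({factor}, Sum)"
    terms = " + ".join([factor_term] + list(covariates))
    fit = smf.ols(f"score ~ {terms}", data=data).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    out = []
    if effect_within is not None:
        tval = fit.tvalues["Intercept"]
        df_den = int(fit.df_resid)
        p = 2 * sps.t.sf(abs(tval), df_den)
        out.append(
            AnovaResult(
                effect=effect_within,
                F=float(tval**2),
                df_num=1,
                df_den=df_den,
                p=float(p),
                statistic=float(tval),
            )
        )
    row = aov.loc[factor_term]
    out.append(
        AnovaResult(
            effect=effect_between,
            F=float(row["F"]),
            df_num=int(row["df"]),
            df_den=int(fit.df_resid),
            p=float(row["PR(>F)"]),
        )
    )
    for c in covariates:
        if effect_within is None:  # covariate terms reported once, on the average
            rowc = aov.loc[c]
            out.append(
                AnovaResult(
                    effect=c,
                    F=float(rowc["F"]),
                    df_num=int(rowc["df"]),
                    df_den=int(fit.df_resid),
                    p=float(rowc["PR(>F)"]),
                )
            )
    return out


def _rm_anova(
    cells: pd.DataFrame,
    info: pd.DataFrame,
    factor: str,
    covariates: Sequence[str],
    prefix: str = "",
) -> list[AnovaResult]:
    """Mixed-design ANOVA for the 2 (cause) x 2 (valence) within design."""
    vp, vn, np_, nn = (cells[c] for c in cells.columns)
    average = (vp + vn + np_ + nn) / 4.0
    cause = (vp + vn - np_ - nn) / 2.0
    valence = (vp - vn + np_ - nn) / 2.0
    interact = (vp - vn - np_ + nn) / 2.0
    res: list[AnovaResult] = []
    res += _contrast_tests(average, info, factor, covariates, f"{prefix}{factor}", None)
    res += _contrast_tests(
        cause, info, factor, covariates, f"{prefix}{factor} x cause", f"{prefix}cause"
    )
    res += _contrast_tests(
        valence, info, factor, covariates, f"{prefix}{factor} x valence", f"{prefix}valence"
    )
    res += _contrast_tests(
        interact,
        info,
        factor,
        covariates,
        f"{prefix}{factor} x cause x valence",
        f"{prefix}cause x valence",
    )
    return res


def _pairwise_posthoc(
    scores: pd.Series,
    info: pd.DataFrame,
    covariates: Sequence[str],
    label: str,
) -> list[AnovaResult]:
    """Pairwise group contrasts with Bonferroni x3 correction."""
    groups = sorted(info["group"].unique())
    out = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            sub = info[info["group"].isin([ga, gb])].join(scores.rename("score")).dropna()
            sub = sub.assign(is_a=(sub["group"] == ga).astype(float))
            terms = " + ".join(["is_a"] + list(covariates))
            fit = smf.ols(f"score ~ {terms}", data=sub).fit()
            t = float(fit.tvalues["is_a"])
            p = float(fit.pvalues["is_a"])
            out.append(
                AnovaResult(
                    effect=f"{label}: {ga} vs {gb}",
                    F=t**2,
                    df_num=1,
                    df_den=int(fit.df_resid),
                    p=p,
                    p_bonf=bonferroni(p),
                    statistic=t,
                    estimate=float(fit.params["is_a"]),
                )
            )
    return out


def cohort_anova(
    endpoints: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "education"),
    lam: float = 0.2,
) -> list[AnovaResult]:
    """The cohort inference: filter endpoints by group, cause and valence.

    Volatility and noise endpoints are Box-Cox transformed (they are
    right-skewed), then decomposed into within-subject contrasts; each
    contrast is analyzed by OLS with group and the (centered) covariates.
    Rows with missing covariates are dropped. Post hoc pairwise group
    contrasts on the volatility and noise scores report Bonferroni x3
    adjusted p values.
    """
    if endpoints["group"].nunique() < 2:
        raise DesignError("cohort_anova needs at least 2 groups")
    df = endpoints.copy()
    df["t_vol"] = boxcox_transform(df["volatility"].to_numpy(), lam)
    df["t_noise"] = boxcox_transform(df["noise"].to_numpy(), lam)
    cells = _wide_cells(df, ("t_vol", "t_noise"))
    info = _between_info(df, "group", covariates).dropna()
    covariates = _usable_covariates(info, covariates)
    res = _rm_anova(cells, info, "group", covariates)
    vol_score = (cells.iloc[:, 0] + cells.iloc[:, 1]) / 2.0
    noise_score = (cells.iloc[:, 2] + cells.iloc[:, 3]) / 2.0
    res += _pairwise_posthoc(vol_score, info, covariates, "volatility")
    res += _pairwise_posthoc(noise_score, info, covariates, "noise")
    return res


def lithium_factor_anova(
    endpoints: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "education"),
    lam: float = 0.2,
) -> list[AnovaResult]:
    """Cohort volatility/noise endpoints with lithium as an additive factor.

    For each valence x cause score (Box-Cox transformed), fits
    ``score ~ group + lithium + covariates`` and reports the group and
    lithium F tests — the naturalistic check of whether ongoing lithium
    treatment, rather than diagnostic group, carries a variability
    difference. Lithium enters additively (not crossed with group) because
    only the BD group contains treated participants.
    """
    if endpoints["lithium"].nunique() < 2:
        raise DesignError("lithium_factor_anova needs both treated and untreated rows")
    df = endpoints.copy()
    df["t_vol"] = boxcox_transform(df["volatility"].to_numpy(), lam)
    df["t_noise"] = boxcox_transform(df["noise"].to_numpy(), lam)
    info = _between_info(df, "group", (*covariates, "lithium")).dropna()
    covariates = _usable_covariates(info, covariates)
    info = info.assign(lithium=info["lithium"].astype(float))
    out = []
    for valence in ("positive", "negative"):
        for cause, col in (("volatility", "t_vol"), ("noise", "t_noise")):
            score = (
                df[df["valence"] == valence]
                .set_index("participant_id")[col]
                .reindex(info.index)
            )
            data = info.join(score.rename("score")).dropna()
            terms = " + ".join(["C(group, Sum)", "lithium", *covariates])
            fit = smf.ols(f"score ~ {terms}", data=data).fit()
            aov = sm.stats.anova_lm(fit, typ=2)
            for label, term in (("group", "C(group, Sum)"), ("lithium", "lithium")):
                row = aov.loc[term]
                out.append(
                    AnovaResult(
                        effect=f"{valence} {cause}: {label}",
                        F=float(row["F"]),
                        df_num=int(row["df"]),
                        df_den=int(fit.df_resid),
                        p=float(row["PR(>F)"]),
                    )
                )
    return out


def summary_stat_anova(
    endpoints: pd.DataFrame,
    stat: str,
    covariates: Sequence[str] = ("age", "sex", "education"),
) -> list[AnovaResult]:
    """Group analysis of a plain summary statistic (mean or SD).

    These are not causes of variability, so the within design has valence
    as its only factor.
    """
    if stat not in ("mean", "sd"):
        raise DesignError("stat must be 'mean' or 'sd'")
    wide = endpoints.pivot_table(
        index="participant_id", columns="valence", values=stat, aggfunc="first"
    )
    info = _between_info(endpoints, "group", covariates).dropna()
    covariates = _usable_covariates(info, covariates)
    average = (wide["positive"] + wide["negative"]) / 2.0
    valence = (wide["positive"] - wide["negative"]) / 2.0
    res = _contrast_tests(average, info, "group", covariates, f"{stat}: group", None)
    res += _contrast_tests(
        valence, info, "group", covariates, f"{stat}: group x valence", f"{stat}: valence"
    )
    return res


def trial_contrast(endpoints: pd.DataFrame) -> list[AnovaResult]:
    """Treatment inference on the trial's change scores.

    A mixed-design ANOVA of the (untransformed) changes in volatility and
    noise with within factors cause x valence and the between factor arm,
    followed by two-sided two-sample t tests of arm on each of the four
    change scores.
    """
    required = {"change_volatility", "change_noise"}
    if not required.issubset(endpoints.columns):
        raise DesignError("trial endpoints must carry change scores")
    bad = endpoints[endpoints[list(required)].isna().any(axis=1)]
    if not bad.empty:
        raise ContractViolationError(
            "missing change scores for participants: "
            + ", ".join(sorted(bad["participant_id"].unique()))
        )
    cells = _wide_cells(endpoints, ("change_volatility", "change_noise"))
    info = _between_info(endpoints, "arm", ())
    res = _rm_anova(cells, info, "arm", (), prefix="treatment: ")
    labels = {
        "change_volatility_positive": "positive volatility",
        "change_volatility_negative": "negative volatility",
        "change_noise_positive": "positive noise",
        "change_noise_negative": "negative noise",
    }
    arm = info["arm"].reindex(cells.index)
    for col, label in labels.items():
        a = cells.loc[arm == "lithium", col].dropna()
        b = cells.loc[arm == "placebo", col].dropna()
        t, p = sps.ttest_ind(a, b, equal_var=True)
        res.append(
            AnovaResult(
                effect=f"arm effect on {label} change",
                F=float(t**2),
                df_num=1,
                df_den=len(a) + len(b) - 2,
                p=float(p),
                statistic=float(t),
                estimate=float(a.mean() - b.mean()),
            )
        )
    return res


# ---------------------------------------------------------------------------
# statsmodels-style wrappers
# ---------------------------------------------------------------------------
class CohortAnalysis:
    """Model object for the cohort workflow (diaries -> group inference)."""

    def __init__(
        self,
        dataset: CohortDataset,
        filter_config: FilterConfig | None = None,
        window_width: int = 50,
        min_ratings: int = 10,
        covariates: Sequence[str] = ("age", "sex", "education"),
        lam: float = 0.2,
    ):
        self.dataset = dataset
        self.filter_config = filter_config
        self.window_width = window_width
        self.min_ratings = min_ratings
        self.covariates = tuple(covariates)
        self.lam = lam

    def fit(self) -> "CohortAnalysisResults":
        endpoints = build_cohort_endpoints(
            self.dataset,
            filter_config=self.filter_config,
            window_width=self.window_width,
            min_ratings=self.min_ratings,
        )
        results = cohort_anova(endpoints, covariates=self.covariates, lam=self.lam)
        results += summary_stat_anova(endpoints, "mean", covariates=self.covariates)
        results += summary_stat_anova(endpoints, "sd", covariates=self.covariates)
        return CohortAnalysisResults(self, endpoints, results)


class CohortAnalysisResults:
    def __init__(self, model: CohortAnalysis, endpoints: pd.DataFrame, results: list[AnovaResult]):
        self.model = model
        self.endpoints = endpoints
        self.anova_results = results

    def result(self, effect: str) -> AnovaResult:
        for r in self.anova_results:
            if r.effect == effect:
                return r
        raise KeyError(effect)

    def group_means(self, column: str) -> pd.Series:
        return self.endpoints.groupby("group")[column].mean()

    def summary(self) -> str:
        frame = results_frame(self.anova_results)
        lines = [
            "Cohort analysis of filter-derived affective variability",
            "=" * 66,
            f"participants: {self.endpoints['participant_id'].nunique()}   "
            f"groups: {', '.join(sorted(self.endpoints['group'].unique()))}",
            f"Box-Cox lambda = {self.model.lam}, covariates = {list(self.model.covariates)}",
            "-" * 66,
            frame.to_string(
                index=False,
                float_format=lambda v: f"{v:.4f}",
                columns=["effect", "F", "df_num", "df_den", "p", "p_bonf"],
            ),
            "=" * 66,
        ]
        return "\n".join(lines)


class TrialAnalysis:
    """Model object for the randomized-trial workflow."""

    def __init__(self, trial: TrialDataset, filter_config: FilterConfig | None = None):
        self.trial = trial
        self.filter_config = filter_config

    def fit(self) -> "TrialAnalysisResults":
        endpoints = build_trial_endpoints(self.trial, filter_config=self.filter_config)
        return TrialAnalysisResults(self, endpoints, trial_contrast(endpoints))


class TrialAnalysisResults:
    def __init__(self, model: TrialAnalysis, endpoints: pd.DataFrame, results: list[AnovaResult]):
        self.model = model
        self.endpoints = endpoints
        self.anova_results = results

    def result(self, effect: str) -> AnovaResult:
        for r in self.anova_results:
            if r.effect == effect:
                return r
        raise KeyError(effect)

    def summary(self) -> str:
        frame = results_frame(self.anova_results)
        lines = [
            "Randomized-trial analysis of filter-derived variability changes",
            "=" * 66,
            f"participants: {self.endpoints['participant_id'].nunique()}   "
            f"arms: {', '.join(sorted(self.endpoints['arm'].unique()))}",
            "-" * 66,
            frame.to_string(
                index=False,
                float_format=lambda v: f"{v:.4f}",
                columns=["effect", "F", "df_num", "df_den", "p", "statistic", "estimate"],
            ),
            "=" * 66,
        ]
        return "\n".join(lines)
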