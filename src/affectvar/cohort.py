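"""Synthetic diary cohorts and a synthetic randomized trial.

The real mood-diary datasets this package is designed for are not publicly
depositable, so this module generates stand-in cohorts with the same
structure and the hypothesized statistical signature:

* a **cohort study** with three groups — bipolar disorder (BD, elevated
  volatility), borderline personality disorder (BPD, elevated noise and
  elevated negative affect) and non-clinical controls (low on both) — rating
  six affect descriptors (anxious, elated, sad, angry, irritable, energetic)
  on a 1–7 Likert scale daily;
* a **randomized trial** of lithium vs placebo in BD, with ten PANAS items
  (five positive, five negative) on a 1–5 scale over a 14-day run-in and a
  28-day treatment period, in which lithium multiplies the volatility of
  positive affect from the first treatment day.

Each participant's diary is produced by the package's own generative model
on a latent 0–1 scale per valence; the day's latent value is mapped to item
ratings by adding item-level Gaussian jitter, affine-scaling to the Likert
range, rounding and clipping. The true generative parameters of every
participant are returned alongside the ratings so that parameter-recovery
can be tested. All output is bit-reproducible given the seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import CohortSpecError, SchemaError
from .generative import GenerativeParams, simulate_subject, _walk_and_observe
from .series import RatingSeries

#: Item sets per instrument, split by valence. The six-descriptor mapping
#: (elated + energetic positive, the rest negative) follows item semantics.
MOODZOOM_ITEMS = {
    "positive": ("elated", "energetic"),
    "negative": ("anxious", "sad", "angry", "irritable"),
}
PANAS_ITEMS = {
    "positive": ("alert", "inspired", "determined", "attentive", "active"),
    "negative": ("upset", "hostile", "ashamed", "nervous", "afraid"),
}
INSTRUMENT_SCALE = {"moodzoom": (1.0, 7.0), "panas": (1.0, 5.0)}
INSTRUMENT_ITEMS = {"moodzoom": MOODZOOM_ITEMS, "panas": PANAS_ITEMS}

#: SD of the per-item Gaussian jitter around the day's latent value,
#: on the latent 0-1 scale.
ITEM_JITTER = 0.05


@dataclass(frozen=True)
class ValenceParams:
    """Hyper-parameters of one group's latent process for one valence.

    Per-subject ``vmu0`` and ``sd0`` are drawn log-normally:
    ``median * exp(sigma * z)`` with standard-normal ``z`` — guaranteeing
    positivity and a realistic right skew of individual variability levels.
    ``mean_affect`` is the group-typical baseline of the latent 0-1 mean.
    """

    vmu_median: float
    vmu_sigma: float
    sd_median: float
    sd_sigma: float
    mean_affect: float


@dataclass(frozen=True)
class GroupSpec:
    """Generation recipe for one cohort group."""

    label: str
    n: int
    positive: ValenceParams
    negative: ValenceParams
    missing_rate: float = 0.15
    lithium_fraction: float = 0.0
    age_mean: float = 40.0
    age_sd: float = 12.0
    female_prop: float = 0.6
    education_probs: tuple[float, ...] = (0.1, 0.2, 0.3, 0.25, 0.15)
    kmu: float = 0.05
    vsd: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 1:
            raise CohortSpecError(f"group {self.label!r}: n must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise CohortSpecError(f"group {self.label!r}: missing_rate must be in [0, 1)")
        if not 0 <= self.lithium_fraction <= 1:
            raise CohortSpecError(f"group {self.label!r}: lithium_fraction must be in [0, 1]")
        if self.lithium_fraction > 0 and self.label != "BD":
            raise CohortSpecError(
                f"group {self.label!r}: lithium_fraction > 0 is only valid for the BD group"
            )
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise CohortSpecError(f"group {self.label!r}: education_probs must sum to 1")


def default_group_specs(
    n_bd: int = 51, n_bpd: int = 33, n_control: int = 51
) -> list[GroupSpec]:
    """The default three-group presets.

    Effect sizes are chosen for clear qualitative structure — BD volatility
    about three times control, BPD noise about twice BD — with the BPD group
    also showing raised negative affect, a higher proportion of women and
    lower educational attainment, mirroring the typical composition of such
    cohorts.
    """
    return [
        GroupSpec(
            label="BD",
            n=n_bd,
            positive=ValenceParams(0.032, 0.4, 0.065, 0.3, 0.45),
            negative=ValenceParams(0.032, 0.4, 0.065, 0.3, 0.28),
            lithium_fraction=0.43,
            female_prop=0.6,
        ),
        GroupSpec(
            label="BPD",
            n=n_bpd,
            positive=ValenceParams(0.013, 0.4, 0.110, 0.3, 0.40),
            negative=ValenceParams(0.013, 0.4, 0.110, 0.3, 0.45),
            female_prop=0.85,
            age_mean=35.0,
            education_probs=(0.25, 0.3, 0.25, 0.15, 0.05),
        ),
        GroupSpec(
            label="control",
            n=n_control,
            positive=ValenceParams(0.010, 0.4, 0.045, 0.3, 0.45),
            negative=ValenceParams(0.010, 0.4, 0.045, 0.3, 0.18),
            female_prop=0.6,
        ),
    ]


@dataclass
class CohortDataset:
    """Item-level ratings, participant covariates and generative truth."""

    items: pd.DataFrame  # participant_id, group, lithium, day, <6 items>
    participants: pd.DataFrame  # participant_id, group, lithium, age, sex, education
    truth: pd.DataFrame  # participant_id, valence, mu0, vmu0, sd0, kmu, vsd
    instrument: str = "moodzoom"


@dataclass
class TrialDataset:
    """Randomized-trial ratings, arm assignments and generative truth."""

    items: pd.DataFrame  # participant_id, arm, day, <10 items>
    participants: pd.DataFrame  # participant_id, arm, age, sex
    truth: pd.DataFrame
    run_in_days: int = 14
    treatment_days: int = 28
    instrument: str = "panas"


def _likert_items(
    latent: np.ndarray,
    item_names: Sequence[str],
    scale: tuple[float, float],
    missing: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Map a latent 0-1 series to jittered, rounded, clipped Likert items."""
    lo, hi = scale
    out = {}
    for name in item_names:
        vals = latent + rng.normal(0.0, ITEM_JITTER, size=latent.size)
        vals = np.clip(np.round(lo + (hi - lo) * vals), lo, hi)
        vals[missing] = np.nan
        out[name] = vals
    return out


def _draw_params(
    vp: ValenceParams, kmu: float, vsd: float, n_days: int, rng: np.random.Generator
) -> GenerativeParams:
    vmu0 = vp.vmu_median * math.exp(vp.vmu_sigma * rng.standard_normal())
    sd0 = vp.sd_median * math.exp(vp.sd_sigma * rng.standard_normal())
    mu0 = float(np.clip(rng.normal(vp.mean_affect, 0.05), 0.05, 0.95))
    return GenerativeParams(
        mu0=mu0, vmu0=vmu0, sd0=sd0, kmu=kmu, vsd=vsd, n_steps=n_days, bounds=(0.0, 1.0)
    )


def generate_cohort(
    specs: Sequence[GroupSpec] | None = None,
    n_days: int = 60,
    seed: int = 0,
) -> CohortDataset:
    """Generate a full three-group diary cohort with truth records.

    Per subject and valence, generative parameters are drawn from the
    group's hyper-distributions, a latent affect process is simulated, and
    the six daily descriptors are produced from the valence-appropriate
    latent day value. Whole days go missing independently with the group's
    ``missing_rate``.
    """
    if specs is None:
        specs = default_group_specs()
    if not specs:
        raise CohortSpecError("specs must be non-empty")
    ss = np.random.SeedSequence(seed)
    item_rows, part_rows, truth_rows = [], [], []
    pid = 0
    for spec in specs:
        for _ in range(spec.n):
            pid += 1
            pid_str = f"P{pid:03d}"
            rng = np.random.default_rng(ss.spawn(1)[0])
            lithium = bool(rng.random() < spec.lithium_fraction)
            age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 18, 75))
            sex = "female" if rng.random() < spec.female_prop else "male"
            education = int(rng.choice(len(spec.education_probs), p=spec.education_probs) + 1)
            missing = rng.random(n_days) < spec.missing_rate
            day_cols = {
                "participant_id": pid_str,
                "group": spec.label,
                "lithium": lithium,
                "day": np.arange(1, n_days + 1),
            }
            for valence, vp in (("positive", spec.positive), ("negative", spec.negative)):
                params = _draw_params(vp, spec.kmu, spec.vsd, n_days, rng)
                _, latent_series = simulate_subject(
                    params, ss.spawn(1)[0], participant_id=pid_str, valence=valence
                )
                day_cols.update(
                    _likert_items(
                        latent_series.values,
                        MOODZOOM_ITEMS[valence],
                        INSTRUMENT_SCALE["moodzoom"],
                        missing,
                        rng,
                    )
                )
                truth_rows.append(
                    {
                        "participant_id": pid_str,
                        "valence": valence,
                        "mu0": params.mu0,
                        "vmu0": params.vmu0,
                        "sd0": params.sd0,
                        "kmu": params.kmu,
                        "vsd": params.vsd,
                    }
                )
            item_rows.append(pd.DataFrame(day_cols))
            part_rows.append(
                {
                    "participant_id": pid_str,
                    "group": spec.label,
                    "lithium": lithium,
                    "age": age,
                    "sex": sex,
                    "education": education,
                }
            )
    return CohortDataset(
        items=pd.concat(item_rows, ignore_index=True),
        participants=pd.DataFrame(part_rows),
        truth=pd.DataFrame(truth_rows),
    )


#: Trial participants are BD patients: reuse the BD cohort preset's
#: volatility/noise medians. The between-subject spread is tighter than in
#: the naturalistic cohort — the trial recruits a narrower population
#: (early presentation, no concurrent treatment).
TRIAL_VALENCE_PARAMS = {
    "positive": ValenceParams(0.032, 0.25, 0.065, 0.25, 0.40),
    "negative": ValenceParams(0.032, 0.25, 0.065, 0.25, 0.30),
}
TRIAL_MISSING_RATE = 0.10


def generate_trial(
    n_per_arm: int = 18,
    lithium_vmu_multiplier: float = 2.0,
    seed: int = 0,
    run_in_days: int = 14,
    treatment_days: int = 28,
) -> TrialDataset:
    """Generate a lithium-vs-placebo trial with a positive-volatility effect.

    Both arms share the same generative hyper-parameters; from the first
    post-randomization day the lithium arm's positive-affect volatility is
    multiplied by ``lithium_vmu_multiplier`` (placebo and negative affect
    are untouched), so a multiplier of 1 is an exact null.
    """
    if n_per_arm < 1:
        raise CohortSpecError("n_per_arm must be >= 1")
    if not lithium_vmu_multiplier > 0:
        raise CohortSpecError("lithium_vmu_multiplier must be > 0")
    n_days = run_in_days + treatment_days
    ss = np.random.SeedSequence(seed)
    item_rows, part_rows, truth_rows = [], [], []
    arms = ["lithium"] * n_per_arm + ["placebo"] * n_per_arm
    for i, arm in enumerate(arms, start=1):
        pid_str = f"T{i:03d}"
        rng = np.random.default_rng(ss.spawn(1)[0])
        age = float(np.clip(rng.normal(35.0, 10.0), 18, 70))
        sex = "female" if rng.random() < 0.55 else "male"
        missing = rng.random(n_days) < TRIAL_MISSING_RATE
        day_cols = {
            "participant_id": pid_str,
            "arm": arm,
            "day": np.arange(1, n_days + 1),
        }
        for valence, vp in TRIAL_VALENCE_PARAMS.items():
            params = _draw_params(vp, 0.05, 0.05, n_days, rng)
            wrng = np.random.default_rng(ss.spawn(1)[0])
            log_vmu = math.log(params.vmu0) + np.concatenate(
                [[0.0], np.cumsum(wrng.normal(0.0, 1.0, size=n_days - 1) * params.kmu)]
            )
            log_sd = math.log(params.sd0) + np.concatenate(
                [[0.0], np.cumsum(wrng.normal(0.0, 1.0, size=n_days - 1) * params.vsd)]
            )
            vmu = np.exp(log_vmu)
            multiplier = 1.0
            if arm == "lithium" and valence == "positive":
                multiplier = lithium_vmu_multiplier
                vmu[run_in_days:] *= multiplier
            _, latent_series = _walk_and_observe(
                params.mu0, vmu, np.exp(log_sd), (0.0, 1.0), wrng, pid_str, valence
            )
            day_cols.update(
                _likert_items(
                    latent_series.values,
                    PANAS_ITEMS[valence],
                    INSTRUMENT_SCALE["panas"],
                    missing,
                    rng,
                )
            )
            truth_rows.append(
                {
                    "participant_id": pid_str,
                    "valence": valence,
                    "mu0": params.mu0,
                    "vmu0": params.vmu0,
                    "sd0": params.sd0,
                    "kmu": params.kmu,
                    "vsd": params.vsd,
                    "vmu_multiplier": multiplier,
                }
            )
        item_rows.append(pd.DataFrame(day_cols))
        part_rows.append(
            {"participant_id": pid_str, "arm": arm, "age": age, "sex": sex}
        )
    return TrialDataset(
        items=pd.concat(item_rows, ignore_index=True),
        participants=pd.DataFrame(part_rows),
        truth=pd.DataFrame(truth_rows),
        run_in_days=run_in_days,
        treatment_days=treatment_days,
    )


def composite_scores(
    items: pd.DataFrame,
    instrument: str,
    participant_id: str | None = None,
) -> tuple[RatingSeries, RatingSeries]:
    """Average the instrument's items into positive and negative series.

    ``items`` holds one participant's rows with a ``day`` column and one
    column per item. A day on which any constituent item is missing is
    marked missing in the composite (no partial averaging).
    """
    if instrument not in INSTRUMENT_ITEMS:
        raise SchemaError(f"unknown instrument {instrument!r}")
    item_map = INSTRUMENT_ITEMS[instrument]
    scale = INSTRUMENT_SCALE[instrument]
    missing_cols = [
        c for cols in item_map.values() for c in cols if c not in items.columns
    ]
    if missing_cols:
        raise SchemaError(f"items table lacks columns {missing_cols}")
    if participant_id is None:
        ids = items["participant_id"].unique() if "participant_id" in items else ["?"]
        participant_id = str(ids[0])
    out = []
    for valence, cols in item_map.items():
        block = items[list(cols)].to_numpy(dtype=float)
        vals = block.mean(axis=1)
        vals[np.isnan(block).any(axis=1)] = np.nan
        out.append(
            RatingSeries(
                participant_id=participant_id,
                valence=valence,
                days=items["day"].to_numpy(),
                values=vals,
                bounds=scale,
            )
        )
    return out[0], out[1]


def dataset_composites(
    items: pd.DataFrame, instrument: str
) -> dict[str, dict[str, RatingSeries]]:
    """Composite positive/negative series for every participant in a table."""
    out: dict[str, dict[str, RatingSeries]] = {}
    for pid, sub in items.groupby("participant_id", sort=False):
        pos, neg = composite_scores(sub, instrument, participant_id=str(pid))
        out[str(pid)] = {"positive": pos, "negative": neg}
    return out
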