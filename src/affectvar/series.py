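"""The observed-data container: one participant's daily ratings of one valence.

A :class:`RatingSeries` holds a daily diary of momentary-affect ratings for a
single participant and valence (positive or negative). Days are 1-based
integer study days; missing days are represented explicitly as NaN so that
downstream consumers (the Bayesian filter, the classic variability metrics)
can distinguish "not rated" from "rated low".
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractViolationError

VALENCES = ("positive", "negative")


@dataclass
class RatingSeries:
    """Daily affect ratings for one participant and one valence.

    Parameters
    ----------
    participant_id : str
        Identifier of the participant.
    valence : str
        Either ``"positive"`` or ``"negative"``.
    days : ndarray of int
        Strictly increasing 1-based study-day indices.
    values : ndarray of float
        Rating on each day; NaN marks a missing day.
    bounds : (float, float)
        The closed rating-scale interval ``[lo, hi]``.
    """

    participant_id: str
    valence: str
    days: np.ndarray
    values: np.ndarray
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        lo, hi = self.bounds
        if not lo < hi:
            raise ContractViolationError(f"bounds must satisfy lo < hi, got {self.bounds}")
        if self.valence not in VALENCES:
            raise ContractViolationError(f"valence must be one of {VALENCES}, got {self.valence!r}")
        if self.days.shape != self.values.shape:
            raise ContractViolationError("days and values must have equal length")
        if self.days.size and np.any(np.diff(self.days) <= 0):
            raise ContractViolationError("days must be strictly increasing")
        obs = self.values[~np.isnan(self.values)]
        if obs.size == 0:
            raise ContractViolationError("series must contain at least one observed rating")
        if np.any(obs < lo) or np.any(obs > hi):
            raise ContractViolationError(
                f"observed values must lie in [{lo}, {hi}]"
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def observed_values(self) -> np.ndarray:
        return self.values[self.observed_mask]

    @property
    def observed_days(self) -> np.ndarray:
        return self.days[self.observed_mask]

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    def __len__(self) -> int:
        return len(self.days)

    # -- transformations ---------------------------------------------------
    def reindex_full(self) -> "RatingSeries":
        """Return a copy indexed on every calendar day from first to last.

        Days absent from ``days`` become explicit NaN entries, so the result
        has one row per calendar day — the shape the filter steps over.
        """
        full = np.arange(self.days[0], self.days[-1] + 1)
        vals = np.full(full.size, np.nan)
        vals[self.days - self.days[0]] = self.values
        return replace(self, days=full, values=vals)

    def normalized(self) -> "RatingSeries":
        """Affinely map ratings onto [0, 1] (missingness preserved)."""
        lo, hi = self.bounds
        return replace(self, values=(self.values - lo) / (hi - lo), bounds=(0.0, 1.0))

    def window(self, start_day: int, end_day: int) -> "RatingSeries":
        """Sub-series restricted to study days ``start_day..end_day`` inclusive."""
        keep = (self.days >= start_day) & (self.days <= end_day)
        return replace(self, days=self.days[keep], values=self.values[keep])

    # -- consecutive-day machinery (shared by the classic metrics) ---------
    def consecutive_pairs(self) -> np.ndarray:
        """(n, 2) array of rating pairs on consecutive observed days."""
        d, v = self.observed_days, self.observed_values
        j = np.where(np.diff(d) == 1)[0]
        return np.column_stack([v[j], v[j + 1]])

    def consecutive_runs(self) -> Iterator[np.ndarray]:
        """Yield maximal runs of ratings on consecutive observed days."""
        d, v = self.observed_days, self.observed_values
        if d.size == 0:
            return
        breaks = np.where(np.diff(d) != 1)[0] + 1
        for chunk in np.split(v, breaks):
            yield chunk

    # -- interchange -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "valence": self.valence,
                "day": self.days,
                "value": self.values,
            }
        )


def series_to_frame(series: Sequence[RatingSeries]) -> pd.DataFrame:
    """Concatenate many series into one long-format frame."""
    return pd.concat([s.to_frame() for s in series], ignore_index=True)
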