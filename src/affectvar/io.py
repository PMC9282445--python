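"""CSV/YAML interchange and run manifests.

All tabular exchange is plain CSV. Ratings travel in long format with the
header ``participant_id,valence,day,value`` (an empty value cell is a
missing day); item-level tables carry one column per instrument item. Runs
executed through the CLI write a JSON manifest (config echo, seed, package
version, row counts) beside their outputs so every artifact is traceable.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import RowValidationError, SchemaError
from .generative import LatentTrajectory
from .series import RatingSeries

RATINGS_COLUMNS = ["participant_id", "valence", "day", "value"]


def write_ratings(series: Sequence[RatingSeries], path: str | Path) -> None:
    """Write many series as one long-format CSV (missing -> empty cell)."""
    frames = [s.to_frame() for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_ratings(
    path: str | Path,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> list[RatingSeries]:
    """Parse a long-format ratings CSV into validated series.

    Out-of-bounds values raise a row-level error carrying the 1-based line
    number (header = line 1). Duplicate (participant, valence, day) rows
    keep the first occurrence with a warning.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"ratings file lacks columns {missing_cols}")
    lo, hi = bounds
    values = df["value"].to_numpy(dtype=float)
    bad = np.where(~np.isnan(values) & ((values < lo) | (values > hi)))[0]
    if bad.size:
        line = int(bad[0]) + 2  # header + 1-based
        raise RowValidationError(line, f"value {values[bad[0]]} outside [{lo}, {hi}]")
    dup = df.duplicated(subset=["participant_id", "valence", "day"], keep="first")
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (participant, valence, day) rows; "
            "keeping the first of each",
            stacklevel=2,
        )
        df = df[~dup]
    out = []
    for (pid, valence), sub in df.groupby(["participant_id", "valence"], sort=False):
        sub = sub.sort_values("day")
        out.append(
            RatingSeries(
                participant_id=str(pid),
                valence=str(valence),
                days=sub["day"].to_numpy(dtype=int),
                values=sub["value"].to_numpy(dtype=float),
                bounds=bounds,
            )
        )
    return out


def write_latent(trajectory: LatentTrajectory, path: str | Path) -> None:
    pd.DataFrame(
        {
            "day": np.arange(1, len(trajectory.mu) + 1),
            "mu": trajectory.mu,
            "vmu": trajectory.vmu,
            "sd": trajectory.sd,
        }
    ).to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


@dataclass
class RunConfig:
    """A run's reproducibility envelope: seed, paths and pipeline knobs.

    YAML schema (all keys optional)::

        seed: 0                    # integer; every stochastic step uses it
        paths:                     # input files, resolved before execution
          ratings: diaries.csv
        instrument: moodzoom       # or panas
        filter:                    # grid sizes of FilterConfig.default
          n_mu: 25
          n_log_vmu: 15
          n_log_sd: 15
          n_kmu: 7
          n_vsd: 7
        pipeline:
          window_width: 50         # days
          min_ratings: 10          # inclusion threshold
          lam: 0.2                 # Box-Cox exponent
          run_in_days: 14          # trial schedule
          treatment_days: 28
    """

    seed: int = 0
    paths: dict = None
    instrument: str = "moodzoom"
    filter: dict = None
    pipeline: dict = None

    def __post_init__(self) -> None:
        self.paths = dict(self.paths or {})
        self.filter = dict(self.filter or {})
        self.pipeline = dict(self.pipeline or {})
        for name, p in self.paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"configured path {name!r} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = read_config(path)
        known = {k: raw[k] for k in ("seed", "paths", "instrument", "filter", "pipeline") if k in raw}
        return cls(**known)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "paths": {k: str(v) for k, v in self.paths.items()},
            "instrument": self.instrument,
            "filter": self.filter,
            "pipeline": self.pipeline,
        }


def write_manifest(
    out_dir: str | Path,
    command: str,
    seed: int | None,
    config: dict | None,
    artifacts: dict[str, int],
) -> Path:
    """Record what a run did: command, seed, config echo, output row counts."""
    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "seed": seed,
        "affectvar_version": __version__,
        "config": config or {},
        "artifacts": artifacts,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
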