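"""Trial-table and manifest I/O.

The trial CSV uses exactly the column model of the analysis (one row per
wall crossing); round-trips are lossless to full float precision.  A
documented column-mapping step adapts externally deposited tables with
different headers to the internal schema.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .study import TRIAL_COLUMNS

__all__ = ["write_trials", "read_trials", "map_columns", "RunManifest"]

_DTYPES = {
    "ID": int, "wIndex": int, "sIndex": int, "NewWalls": int,
    "Task": str, "Stage": str, "Group": str,
}


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write the trial table as CSV with the canonical header."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial CSV, validating the header exactly."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if missing or extra:
        raise ValueError(
            f"malformed trial header: missing={missing}, extra={extra}"
        )
    for col, typ in _DTYPES.items():
        df[col] = df[col].astype(typ)
    return df[TRIAL_COLUMNS]


def map_columns(df: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Rename an external table's columns to the internal schema.

    ``mapping`` maps external header names to internal ones; unmapped
    internal columns must already be present or are reported as missing.
    """
    out = df.rename(columns=dict(mapping))
    missing = [c for c in TRIAL_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(
            f"mapped table is still missing internal columns: {missing}"
        )
    return out[TRIAL_COLUMNS]


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seeds, outputs."""

    config: dict[str, Any]
    seed: int
    version: str
    outputs: list[str] = dataclasses.field(default_factory=list)
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds")
    )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonable)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")
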