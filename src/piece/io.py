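"""Trial-table file I/O, run configuration and provenance sidecars.

Trial tables are comma-delimited UTF-8 text with a header row; angles in
degrees, counter-clockwise positive, target at 0 degrees.  A
column-mapping option accommodates externally deposited tables whose
schema differs from ours.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

REQUIRED_COLUMNS = [
    "participant_id",
    "trial_index",
    "block",
    "phase",
    "trial_type",
    "rotation_deg",
    "feedback",
    "hand_angle_deg",
]
OPTIONAL_COLUMNS = ["cursor_angle_deg", "target_jump_deg", "excluded"]
ANGLE_COLUMNS = ["rotation_deg", "hand_angle_deg"]
EXPECTED_ROTATIONS = (-4.0, -2.0, 0.0, 2.0, 4.0)


class TrialTableError(ValueError):
    """Raised when a trial table fails validation."""


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline invocation."""

    model: str = "PIECE"
    seed: int = 1
    params: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    analysis: dict = field(
        default_factory=lambda: {"z_threshold": 3.5, "n_ige_bins": 5, "n_boot": 10_000}
    )
    fit: dict = field(default_factory=lambda: {"n_starts": 20})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def read_trials(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a trial table.

    ``column_map`` renames external column names to ours (external -> ours)
    before validation.  Raises on missing columns, non-numeric or
    non-finite angles; warns on unexpected rotation levels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # keep_default_na: 'null' is a trial type here, not a missing value
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    if df.empty:
        raise TrialTableError(f"{path}: empty trial table")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing required column(s) {missing}")
    for col in ANGLE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[~np.isfinite(vals)]
        if len(bad):
            raise TrialTableError(
                f"{path}: non-numeric or non-finite {col} at row {int(bad[0]) + 2}"
            )
        df[col] = vals.astype(float)
    if "excluded" not in df.columns:
        df["excluded"] = False
    df["excluded"] = df["excluded"].astype(bool)
    measured = df[df["trial_type"] == "measured"]
    odd = sorted(set(measured["rotation_deg"]) - set(EXPECTED_ROTATIONS))
    if odd:
        warnings.warn(f"{path}: unexpected rotation level(s) on measured trials: {odd}")
    nulls = df[df["trial_type"] == "null"]
    if (nulls["rotation_deg"] != 0).any():
        warnings.warn(f"{path}: null trials with nonzero rotation")
    return df


def write_trials(table: pd.DataFrame, path, sidecar: dict | None = None) -> None:
    """Write a trial table as CSV (deterministic column order, 8 sig digits).

    When ``sidecar`` is given, a ``<path>.provenance.json`` file with the
    supplied metadata (e.g. config hash and seed) is written next to it.
    """
    path = Path(path)
    cols = [c for c in ["participant_id", *REQUIRED_COLUMNS[1:], *OPTIONAL_COLUMNS]
            if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, float_format="%.8g")
    if sidecar is not None:
        Path(str(path) + ".provenance.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )
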