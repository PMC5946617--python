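"""CSV schema for adjustment tables and run configuration.

The adjustment table is a plain UTF-8, comma-separated CSV with dot
decimals and the header

    observer_id,stimulus_id,condition,task,repeat_index,chroma_x,chroma_y

one row per colour adjustment.  The colour-neutral disk is a regular
stimulus row with ``condition="disk"`` and ``task="grey"``; uniform and
textured disks are pooled under a single stimulus id.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import pydantic
from pydantic import BaseModel, ConfigDict, Field

from .errors import ConfigError, DataFormatError

__all__ = [
    "COLUMNS",
    "CONDITIONS",
    "TASKS",
    "RunConfig",
    "read_adjustments",
    "write_adjustments",
    "validate_adjustments",
]

COLUMNS = [
    "observer_id", "stimulus_id", "condition", "task", "repeat_index",
    "chroma_x", "chroma_y",
]
CONDITIONS = {"photo", "outline", "painted", "disk", "other"}
TASKS = {"typical", "grey"}
KEY = ["observer_id", "stimulus_id", "condition", "task", "repeat_index"]


class RunConfig(BaseModel):
    """Analysis configuration for :func:`memcolour.pipeline.run_pipeline`.

    Unknown keys are rejected.  ``epsilon=None`` keeps zero-variance cues
    strict (the affected cell is skipped with a logged reason); a small
    positive value opts in to regularised reliabilities.
    """

    model_config = ConfigDict(extra="forbid")

    levels: list[Literal["individual", "pooled", "aggregated"]] = Field(
        default_factory=lambda: ["individual", "pooled", "aggregated"]
    )
    tail: Literal["one_tailed_positive", "two_tailed"] = "one_tailed_positive"
    exclude: list[str] = Field(default_factory=list)
    include_relative: bool = True
    centre_predicted: bool = False
    epsilon: Optional[float] = Field(default=None, gt=0)
    clamp_degenerate: bool = True
    sd_mode: Literal["sqrt", "inverse"] = "sqrt"
    hue_axis_scope: Literal["auto", "per_observer", "global"] = "auto"
    disk_stimulus_id: str = "disk"
    out_dir: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            return cls.model_validate(json.loads(Path(path).read_text()))
        except (json.JSONDecodeError, pydantic.ValidationError) as exc:
            raise ConfigError(f"invalid run config {path}: {exc}") from exc


def validate_adjustments(
    df: pd.DataFrame, disk_stimulus_id: str = "disk"
) -> pd.DataFrame:
    """Validate an adjustments table; returns a typed copy.

    Error messages name the offending data row (1-based, excluding the
    header) and column.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"missing columns: {missing}")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        raise DataFormatError(f"unknown columns: {extra}")
    out = df.loc[:, COLUMNS].copy().reset_index(drop=True)

    for col in ("observer_id", "stimulus_id", "condition", "task"):
        out[col] = out[col].astype(str)
    try:
        out["repeat_index"] = out["repeat_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise DataFormatError(f"column repeat_index is not integer: {exc}") from exc
    for col in ("chroma_x", "chroma_y"):
        try:
            out[col] = out[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise DataFormatError(f"column {col} is not numeric: {exc}") from exc

    def _first_bad(mask: pd.Series, col: str, what: str) -> None:
        if mask.any():
            row = int(mask.idxmax()) + 1
            raise DataFormatError(f"row {row}, column {col}: {what} "
                                  f"({out.loc[row - 1, col]!r})")

    _first_bad(~out["condition"].isin(CONDITIONS), "condition", "unknown condition")
    _first_bad(~out["task"].isin(TASKS), "task", "unknown task")
    _first_bad(out["repeat_index"] < 1, "repeat_index", "must be >= 1")
    for col in ("chroma_x", "chroma_y"):
        _first_bad(~np.isfinite(out[col]), col, "non-finite value")

    dup = out.duplicated(subset=KEY, keep="first")
    if dup.any():
        row = int(dup.idxmax()) + 1
        raise DataFormatError(
            f"row {row}: duplicate (observer, stimulus, condition, task, repeat) key "
            f"{tuple(out.loc[row - 1, KEY])}"
        )

    is_disk_cond = out["condition"] == "disk"
    is_disk_id = out["stimulus_id"] == disk_stimulus_id
    _first_bad(is_disk_cond & ~is_disk_id, "stimulus_id",
               f"condition 'disk' requires stimulus_id {disk_stimulus_id!r}")
    _first_bad(is_disk_id & ~is_disk_cond, "condition",
               f"stimulus_id {disk_stimulus_id!r} requires condition 'disk'")
    _first_bad(is_disk_cond & (out["task"] != "grey"), "task",
               "disk rows must have task 'grey'")
    return out


def read_adjustments(
    path: str | Path, disk_stimulus_id: str = "disk"
) -> pd.DataFrame:
    """Read and validate an adjustments CSV."""
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype={"observer_id": str, "stimulus_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc
    return validate_adjustments(df, disk_stimulus_id=disk_stimulus_id)


def write_adjustments(df: pd.DataFrame, path: str | Path) -> None:
    """Write an adjustments table as CSV (validates first)."""
    validate_adjustments(df).to_csv(path, index=False)


def write_csv_rows(rows: Sequence[dict], path: str | Path) -> None:
    """Write a list of dict rows as a CSV (helper for results tables)."""
    pd.DataFrame(rows).to_csv(path, index=False)
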