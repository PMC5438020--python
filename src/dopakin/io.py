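"""File formats: TAC CSV, cohort CSV, schedule YAML, JSON reports.

Files store time in seconds; all kinetic computation is in minutes, with
the conversion confined to this boundary. CSVs are comma-separated, UTF-8,
'.' decimal, header row required.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ARM_CHALLENGE, ARM_TEST_RETEST
from .errors import FormatError
from .schedules import SCHEDULE_PRESETS, FrameSchedule, make_schedule
from .simulate import TimeActivityCurve

__all__ = [
    "read_tac_csv",
    "write_tac_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_schedule_spec",
    "write_json_report",
]

TAC_COLUMNS = ["frame_start_s", "frame_duration_s", "activity_kbq_ml"]
COHORT_COLUMNS = [
    "subject_id",
    "arm",
    "dose_label",
    "ki_scan1",
    "ki_scan2",
    "ki_true_scan1",
    "interval_days",
]
_VALID_ARMS = {ARM_TEST_RETEST, ARM_CHALLENGE}


def read_tac_csv(path: str | Path, region_label: str | None = None) -> TimeActivityCurve:
    """Read a single-region TAC CSV (frame_start_s, frame_duration_s,
    activity_kbq_ml); schedule invariants are enforced on load."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # noqa: BLE001 - wrap any parser failure
        raise FormatError(f"{path}: cannot parse CSV ({e})") from e
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in TAC_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: column {col!r} is not numeric")
    start = df["frame_start_s"].to_numpy(dtype=float)
    dur = df["frame_duration_s"].to_numpy(dtype=float)
    if np.any(dur <= 0):
        row = int(np.argmax(dur <= 0))
        raise FormatError(f"{path}: row {row}: non-positive frame_duration_s")
    if start.size > 1:
        gap = start[1:] - (start[:-1] + dur[:-1])
        if np.any(np.abs(gap) > 1e-6):
            row = int(np.argmax(np.abs(gap) > 1e-6)) + 1
            raise FormatError(f"{path}: row {row}: frames overlap or leave a gap")
    try:
        schedule = FrameSchedule(start_s=start, duration_s=dur)
    except Exception as e:
        raise FormatError(f"{path}: {e}") from e
    label = region_label if region_label is not None else path.stem
    return TimeActivityCurve(
        schedule=schedule,
        activity=df["activity_kbq_ml"].to_numpy(dtype=float),
        region_label=label,
    )


def write_tac_csv(tac: TimeActivityCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame_start_s": tac.schedule.start_s,
            "frame_duration_s": tac.schedule.duration_s,
            "activity_kbq_ml": tac.activity,
        }
    ).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-subject Ki table."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse CSV ({e})") from e
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise FormatError(f"{path}: duplicate subject_id {dup!r}")
    bad_arm = set(df["arm"]) - _VALID_ARMS
    if bad_arm:
        raise FormatError(f"{path}: unknown arm label(s) {sorted(bad_arm)}")
    for col in ("ki_scan1", "ki_scan2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            raise FormatError(f"{path}: column {col!r} must be numeric and positive")
    return df[COHORT_COLUMNS].copy()


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def load_schedule_spec(source: str | Path | list) -> FrameSchedule:
    """Resolve a schedule from a preset name, a YAML/JSON file or an inline
    list of ``{count, duration_s}`` mappings."""
    if isinstance(source, str) and source in SCHEDULE_PRESETS:
        return make_schedule(SCHEDULE_PRESETS[source])
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, list):
        raise FormatError("schedule spec must be a preset name or a list of {count, duration_s}")
    try:
        spec = [(int(item["count"]), float(item["duration_s"])) for item in source]
    except (KeyError, TypeError, ValueError) as e:
        raise FormatError(f"malformed schedule spec entry: {e}") from e
    return make_schedule(spec)


def write_json_report(report: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
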