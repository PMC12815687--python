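"""Readers/writers for every pipeline artifact.

All artifacts are plain UTF-8 CSV/TSV with mandatory headers and '.'
decimals.  Readers validate the documented schema and raise ``SchemaError``
naming the offending column or value; unknown extra columns are preserved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import GROUPS, FrameSchedule, InputFunction

__all__ = [
    "SchemaError",
    "read_participants",
    "write_participants",
    "read_vt_table",
    "write_vt_table",
    "read_input_function",
    "write_input_function",
    "read_schedule",
    "write_schedule",
    "read_tacs",
    "write_tacs",
    "read_fits",
    "write_fits",
]


class SchemaError(ValueError):
    """An artifact file does not conform to its documented schema."""


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    for c in columns:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric value in column {c!r} at row {bad[0]}")
        df[c] = coerced
    return df


# -- participants ------------------------------------------------------------

def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ["participant_id", "group", "age", "sex"], path)
    bad = sorted(set(df["group"].astype(str)) - set(GROUPS))
    if bad:
        raise SchemaError(f"{path}: unknown group label(s) {bad}; allowed {list(GROUPS)}")
    if df["participant_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicated participant_id")
    return _numeric(df, ["age"], path)


def write_participants(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# -- V_T (and other parameter) tables ---------------------------------------

def read_vt_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ["participant_id"], path)
    df = df.set_index("participant_id")
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: no ROI columns")
    return _numeric(df, list(df.columns), path)


def write_vt_table(df: pd.DataFrame, path) -> None:
    # %.17g guarantees binary round-trip of float64 through the text format
    df.rename_axis("participant_id").to_csv(path, float_format="%.17g")


# -- input function ----------------------------------------------------------

def read_input_function(path) -> InputFunction:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require(df, ["time_min", "parent_plasma", "whole_blood"], path)
    df = _numeric(df, ["time_min", "parent_plasma", "whole_blood"], path)
    try:
        return InputFunction(df["time_min"].to_numpy(), df["parent_plasma"].to_numpy(),
                             df["whole_blood"].to_numpy())
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_input_function(inp: InputFunction, path) -> None:
    pd.DataFrame({
        "time_min": inp.sample_times_min,
        "parent_plasma": inp.plasma_activity,
        "whole_blood": inp.wholeblood_activity,
    }).to_csv(path, sep="\t", index=False)


# -- frame schedule ----------------------------------------------------------

def read_schedule(path) -> FrameSchedule:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require(df, ["frame_start_s", "frame_duration_s"], path)
    df = _numeric(df, ["frame_start_s", "frame_duration_s"], path)
    try:
        return FrameSchedule(df["frame_start_s"].to_numpy(), df["frame_duration_s"].to_numpy())
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_schedule(schedule: FrameSchedule, path) -> None:
    pd.DataFrame({
        "frame_start_s": schedule.frame_start_s,
        "frame_duration_s": schedule.frame_duration_s,
    }).to_csv(path, sep="\t", index=False)


# -- per-participant TACs ----------------------------------------------------

def read_tacs(path) -> tuple[FrameSchedule, pd.DataFrame]:
    """TAC TSV: frame_start_s, frame_duration_s, one column per ROI (kBq/mL)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require(df, ["frame_start_s", "frame_duration_s"], path)
    df = _numeric(df, list(df.columns), path)
    try:
        schedule = FrameSchedule(df["frame_start_s"].to_numpy(), df["frame_duration_s"].to_numpy())
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    rois = df.drop(columns=["frame_start_s", "frame_duration_s"])
    if rois.shape[1] == 0:
        raise SchemaError(f"{path}: no ROI activity columns")
    return schedule, rois


def write_tacs(schedule: FrameSchedule, tacs: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "frame_start_s": schedule.frame_start_s,
        "frame_duration_s": schedule.frame_duration_s,
    })
    pd.concat([out, tacs.reset_index(drop=True)], axis=1).to_csv(path, sep="\t", index=False)


# -- kinetic fits ------------------------------------------------------------

_FIT_COLUMNS = ["participant_id", "roi", "K1", "k2", "k3", "k4", "Vb", "VT", "rss", "converged"]


def read_fits(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, _FIT_COLUMNS, path)
    df = _numeric(df, ["K1", "k2", "k3", "k4", "Vb", "VT", "rss"], path)
    df["converged"] = df["converged"].astype(bool)
    return df


def write_fits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def fits_to_parameter_tables(fits: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pivot the tidy fits table into per-parameter participants x ROI tables."""
    out = {}
    for par in ("VT", "K1", "Vb"):
        out[par] = fits.pivot(index="participant_id", columns="roi", values=par)
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
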