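"""Quality control on parameter tables: outlier detection, participant
exclusion and mean imputation.

A cell is an outlier when it lies more than ``k_sd`` sample standard
deviations (default 3) from the pooled whole-sample mean of its ROI column.
A participant is considered for exclusion when at least ``fraction`` (default
50%) of their cells are flagged.  Flagged network-input cells are imputed
with the mean of the same ROI over all other participants, restricted to
unflagged donors so one outlier cannot contaminate another's replacement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "detect_outliers",
    "exclusion_rule",
    "impute_outliers",
    "apply_enrolment_exclusions",
    "run_qc",
]


class ImputationError(ValueError):
    """A flagged column has too few unflagged donors to impute from."""


@dataclass
class QCReport:
    """Bookkeeping of every QC action taken on a run."""

    outlier_mask: dict[str, pd.DataFrame] = field(default_factory=dict)
    excluded_participants: list[dict] = field(default_factory=list)
    imputed_cells: list[dict] = field(default_factory=list)
    k_sd: float = 3.0
    exclude_fraction: float = 0.5

    def n_flagged(self, parameter: str) -> int:
        return int(self.outlier_mask[parameter].to_numpy().sum())

    def to_dict(self) -> dict:
        return {
            "k_sd": self.k_sd,
            "exclude_fraction": self.exclude_fraction,
            "n_flagged": {p: self.n_flagged(p) for p in self.outlier_mask},
            "flagged_cells": {
                p: [
                    {"participant_id": str(m.index[i]), "roi": str(m.columns[j])}
                    for i, j in zip(*np.nonzero(m.to_numpy()))
                ]
                for p, m in self.outlier_mask.items()
            },
            "excluded_participants": list(self.excluded_participants),
            "imputed_cells": list(self.imputed_cells),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def detect_outliers(table: pd.DataFrame, k_sd: float = 3.0) -> pd.DataFrame:
    """Boolean mask: |x - column mean| > k_sd * column SD, computed over the
    whole pooled sample per ROI (sample SD, n-1 denominator).

    A zero-variance column flags nothing (documented convention).
    """
    if len(table) < 3:
        raise ValueError("outlier detection needs at least 3 rows")
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        mask = (table - mean).abs() > k_sd * sd
    return (mask & (sd > 0)).astype(bool)


def exclusion_rule(outlier_mask: pd.DataFrame, fraction: float = 0.5) -> list[str]:
    """Participants whose flagged-cell share is at least ``fraction`` (a
    closed >= comparison: 'at least 50%')."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if outlier_mask.size == 0:
        return []
    share = outlier_mask.mean(axis=1)
    return [str(i) for i in outlier_mask.index[share >= fraction]]


def impute_outliers(
    table: pd.DataFrame, outlier_mask: pd.DataFrame
) -> tuple[pd.DataFrame, list[dict]]:
    """Replace each flagged cell with the mean of its ROI over all other
    participants, restricted to unflagged donors.

    Returns the imputed table and a record of every replaced cell.
    """
    if not table.index.equals(outlier_mask.index) or not table.columns.equals(outlier_mask.columns):
        raise ValueError("table and outlier mask must share index and columns")
    out = table.copy()
    records: list[dict] = []
    for col in table.columns[outlier_mask.any(axis=0)]:
        flagged = outlier_mask[col]
        donors = table.loc[~flagged, col]
        if len(donors) < 2:
            raise ImputationError(f"column {col!r} has {len(donors)} unflagged donors; need >= 2")
        for pid in table.index[flagged]:
            donor_mean = float(donors.drop(index=pid, errors="ignore").mean())
            records.append({
                "participant_id": str(pid),
                "roi": str(col),
                "original": float(table.at[pid, col]),
                "imputed": donor_mean,
            })
            out.at[pid, col] = donor_mean
    return out, records


def apply_enrolment_exclusions(
    participants: pd.DataFrame,
    exclusions: Sequence[tuple[str, str]] | Mapping[str, str],
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop listed participants (id, reason) before any analysis — e.g.
    missing arterial blood data or an incomplete acquisition — and record why.
    """
    items = list(exclusions.items()) if isinstance(exclusions, Mapping) else list(exclusions)
    ids = {pid for pid, _ in items}
    missing = ids - set(participants["participant_id"].astype(str))
    if missing:
        raise KeyError(f"exclusion list names unknown participants: {sorted(missing)}")
    records = [{"participant_id": str(pid), "reason": reason} for pid, reason in items]
    retained = participants[~participants["participant_id"].astype(str).isin(ids)].reset_index(drop=True)
    return retained, records


def run_qc(
    parameter_tables: Mapping[str, pd.DataFrame],
    k_sd: float = 3.0,
    exclude_fraction: float = 0.5,
    impute_parameter: str = "VT",
) -> tuple[pd.DataFrame, QCReport]:
    """Full QC pass over per-parameter participants x ROI tables.

    Outlier masks are computed for every parameter (typically VT, K1, Vb);
    the exclusion rule is applied to all masks stacked side by side (all
    parameters were assessed for outliers); only the network-input parameter
    (``impute_parameter``, V_T by default) is imputed.  Returns the cleaned
    V_T table (excluded participants dropped, flagged cells imputed) and the
    QC report.
    """
    if impute_parameter not in parameter_tables:
        raise KeyError(f"{impute_parameter!r} not among parameter tables {list(parameter_tables)}")
    report = QCReport(k_sd=k_sd, exclude_fraction=exclude_fraction)
    for name, tab in parameter_tables.items():
        report.outlier_mask[name] = detect_outliers(tab, k_sd=k_sd)
    stacked = pd.concat(
        [m.add_prefix(f"{p}:") for p, m in report.outlier_mask.items()], axis=1
    )
    excluded = exclusion_rule(stacked, fraction=exclude_fraction)
    report.excluded_participants = [
        {"participant_id": pid,
         "reason": f">= {exclude_fraction:.0%} of parameter values outside mean +/- {k_sd:g} SD"}
        for pid in excluded
    ]
    vt = parameter_tables[impute_parameter].drop(index=excluded)
    mask = report.outlier_mask[impute_parameter].drop(index=excluded)
    clean, records = impute_outliers(vt, mask)
    report.imputed_cells = records
    return clean, report
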