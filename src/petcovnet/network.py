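"""Single-participant covariance perturbation networks.

The method builds a reference partial-correlation network from the healthy
control (HC) group, then measures how much the network changes when one
patient is added ("perturbed" network).  The edge-wise change DeltaPCC is
standardised into a z-score,

    Z = DeltaPCC / sigma,    sigma = (1 - PCC_ref^2) / (n - 1),

where PCC_ref is the reference edge correlation and n the reference-group
size; under the null (the added participant comes from the reference
population) DeltaPCC has mean 0.  HC participants get their own Z matrices by
jackknife: the reference is rebuilt on the remaining n-1 controls and the
"perturbed" network is the full-group network.

Partial correlations are Pearson correlations of the ROI columns after
ordinary-least-squares residualisation on an intercept plus covariates (age,
mean-centred, and sex coded 0/1 by convention here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import HIPPOCAMPUS

__all__ = [
    "ReferenceNetwork",
    "DeltaNetwork",
    "ZMatrix",
    "InfiniteVarianceError",
    "encode_covariates",
    "partial_correlation_matrix",
    "build_reference_network",
    "perturbed_network",
    "delta_network",
    "zscore_network",
    "participant_zscores",
    "jackknife_reference_z",
    "extreme_deviation_proportion",
    "edge_subset",
    "zmatrices_to_long",
]

#: below this reference-group size the large-n null approximation for
#: DeltaPCC is questionable; the analysis warns but proceeds
LARGE_N_GUIDELINE = 28


class InfiniteVarianceError(ValueError):
    """An off-diagonal reference edge has |PCC| = 1, so sigma_DeltaPCC = 0."""


@dataclass(frozen=True)
class ReferenceNetwork:
    """Partial-correlation matrix of the reference group plus its size."""

    pcc: pd.DataFrame
    n: int
    covariate_names: tuple[str, ...] = ()

    @property
    def roi_names(self) -> tuple[str, ...]:
        return tuple(self.pcc.columns)


@dataclass(frozen=True)
class DeltaNetwork:
    """Edge-wise network change caused by adding one participant."""

    dpcc: pd.DataFrame
    participant_id: str


@dataclass(frozen=True)
class ZMatrix:
    """Edge-wise deviation z-scores of one participant from the reference."""

    z: pd.DataFrame
    participant_id: str
    reference_n: int

    def edge_pvalues(self) -> pd.DataFrame:
        """Two-sided per-edge p = 2*(1 - Phi(|Z|)); diagonal left at 1."""
        p = 2.0 * sps.norm.sf(np.abs(self.z.to_numpy()))
        np.fill_diagonal(p, 1.0)
        return pd.DataFrame(p, index=self.z.index, columns=self.z.columns)


def encode_covariates(participants: pd.DataFrame, names: tuple[str, ...] | list[str]) -> pd.DataFrame:
    """Numeric covariate design: age mean-centred, sex F/M coded 0/1."""
    cols = {}
    for name in names:
        col = participants[name]
        if name == "sex" or col.dtype == object:
            levels = sorted(col.astype(str).unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {name!r} has more than two levels: {levels}")
            cols[name] = (col.astype(str) == levels[-1]).astype(float)
        else:
            cols[name] = col.astype(float) - float(col.mean())
    out = pd.DataFrame(cols)
    idx = participants["participant_id"] if "participant_id" in participants else participants.index
    out.index = pd.Index(idx, name="participant_id")
    return out


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = y.shape[0]
    x = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def partial_correlation_matrix(
    roi_values: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """ROI x ROI partial Pearson correlations after OLS residualisation of
    every column on an intercept plus the covariates."""
    y = roi_values.to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("ROI table contains missing values; run QC imputation first")
    c = None
    n_cov = 0
    if covariates is not None and covariates.shape[1] > 0:
        if len(covariates) != len(roi_values):
            raise ValueError("covariates must align row-wise with the ROI table")
        c = covariates.to_numpy(dtype=float)
        n_cov = c.shape[1]
    if len(roi_values) < n_cov + 3:
        raise ValueError(f"need at least {n_cov + 3} rows for {n_cov} covariates")
    resid = _residualize(y, c)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(resid, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=roi_values.columns, columns=roi_values.columns)


def build_reference_network(
    hc_table: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> ReferenceNetwork:
    """Reference network from the control group's V_T table."""
    n = len(hc_table)
    if n < 5:
        raise ValueError(f"reference group of {n} is too small; the deviation statistic needs n >= 5")
    if n < LARGE_N_GUIDELINE:
        warnings.warn(
            f"reference group n={n} is below the n>={LARGE_N_GUIDELINE} guideline for the "
            "large-sample null approximation; proceeding",
            UserWarning,
            stacklevel=2,
        )
    pcc = partial_correlation_matrix(hc_table, covariates)
    names = tuple(covariates.columns) if covariates is not None else ()
    return ReferenceNetwork(pcc=pcc, n=n, covariate_names=names)


def perturbed_network(
    reference_table: pd.DataFrame,
    participant_row: pd.Series,
    reference_covariates: pd.DataFrame | None = None,
    participant_covariates: pd.Series | None = None,
    freeze_reference_coefficients: bool = False,
) -> pd.DataFrame:
    """Partial-correlation network of the reference group plus one added
    participant; the covariate regression is refit on the stacked n+1 sample
    (set ``freeze_reference_coefficients`` to reuse the reference-only fit).
    """
    if not set(reference_table.columns) <= set(participant_row.index):
        raise ValueError("participant row is missing ROI values present in the reference table")
    row = participant_row[reference_table.columns].astype(float)
    stacked = pd.concat([reference_table, row.to_frame().T])
    cov = None
    if reference_covariates is not None:
        if participant_covariates is None:
            raise ValueError("participant covariates required when the reference has covariates")
        crow = participant_covariates[reference_covariates.columns].astype(float)
        cov = pd.concat([reference_covariates, crow.to_frame().T])
    if not freeze_reference_coefficients:
        return partial_correlation_matrix(stacked, cov)
    # freeze: residualise the stacked data with coefficients fit on the reference only
    y_ref = reference_table.to_numpy(dtype=float)
    n = y_ref.shape[0]
    x_ref = np.ones((n, 1)) if cov is None else np.column_stack(
        [np.ones(n), reference_covariates.to_numpy(dtype=float)]
    )
    beta, *_ = np.linalg.lstsq(x_ref, y_ref, rcond=None)
    y_all = stacked.to_numpy(dtype=float)
    x_all = np.ones((n + 1, 1)) if cov is None else np.column_stack(
        [np.ones(n + 1), cov.to_numpy(dtype=float)]
    )
    resid = y_all - x_all @ beta
    corr = np.clip(np.corrcoef(resid, rowvar=False), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=reference_table.columns, columns=reference_table.columns)


def delta_network(perturbed: pd.DataFrame, reference: ReferenceNetwork, participant_id: str) -> DeltaNetwork:
    """DeltaPCC = perturbed - reference, the edge-wise network change."""
    if not perturbed.columns.equals(reference.pcc.columns):
        raise ValueError("perturbed and reference networks must share the ROI set")
    return DeltaNetwork(dpcc=perturbed - reference.pcc, participant_id=participant_id)


def zscore_network(delta: DeltaNetwork, reference: ReferenceNetwork) -> ZMatrix:
    """Standardise DeltaPCC by sigma = (1 - PCC_ref^2)/(n - 1) per edge."""
    if reference.n < 3:
        raise ValueError("reference group must have n >= 3")
    if not delta.dpcc.columns.equals(reference.pcc.columns):
        raise ValueError("delta and reference networks must share the ROI set")
    pcc = reference.pcc.to_numpy()
    off = ~np.eye(pcc.shape[0], dtype=bool)
    saturated = off & (np.abs(pcc) >= 1.0 - 1e-12)
    if saturated.any():
        i, j = np.nonzero(saturated)
        edges = [(str(reference.pcc.index[a]), str(reference.pcc.columns[b])) for a, b in zip(i, j)]
        raise InfiniteVarianceError(
            f"reference |PCC| = 1 on off-diagonal edges {edges[:6]}; sigma_DeltaPCC is zero there"
        )
    sigma = (1.0 - pcc**2) / (reference.n - 1)
    np.fill_diagonal(sigma, 1.0)  # diagonal DeltaPCC is 0; Z forced to 0 below
    z = delta.dpcc.to_numpy() / sigma
    np.fill_diagonal(z, 0.0)
    return ZMatrix(
        z=pd.DataFrame(z, index=reference.pcc.index, columns=reference.pcc.columns),
        participant_id=delta.participant_id,
        reference_n=reference.n,
    )


def participant_zscores(
    hc_table: pd.DataFrame,
    patient_table: pd.DataFrame,
    hc_covariates: pd.DataFrame | None = None,
    patient_covariates: pd.DataFrame | None = None,
) -> list[ZMatrix]:
    """One perturbation Z matrix per non-reference participant."""
    reference = build_reference_network(hc_table, hc_covariates)
    out = []
    for pid in patient_table.index:
        pcov = patient_covariates.loc[pid] if patient_covariates is not None else None
        pert = perturbed_network(hc_table, patient_table.loc[pid], hc_covariates, pcov)
        out.append(zscore_network(delta_network(pert, reference, str(pid)), reference))
    return out


def jackknife_reference_z(
    hc_table: pd.DataFrame, hc_covariates: pd.DataFrame | None = None
) -> list[ZMatrix]:
    """Leave-one-out Z matrices for the reference group itself.

    For each control: the reference is the network on the remaining n-1
    participants and the perturbed network is the full-group network, so the
    held-out participant plays the role of the added one.
    """
    n = len(hc_table)
    if n < 6:
        raise ValueError("jackknife needs at least 6 reference participants")
    full = partial_correlation_matrix(hc_table, hc_covariates)
    out = []
    for pid in hc_table.index:
        sub = hc_table.drop(index=pid)
        subcov = hc_covariates.drop(index=pid) if hc_covariates is not None else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            ref = build_reference_network(sub, subcov)
        out.append(zscore_network(delta_network(full, ref, str(pid)), ref))
    return out


def extreme_deviation_proportion(zmatrix: ZMatrix, z_crit: float = 1.96) -> pd.Series:
    """Per ROI, the fraction of its incident edges with |Z| > z_crit."""
    if z_crit <= 0:
        raise ValueError("z_crit must be positive")
    z = zmatrix.z.to_numpy()
    r = z.shape[0]
    extreme = np.abs(z) > z_crit
    np.fill_diagonal(extreme, False)
    return pd.Series(extreme.sum(axis=1) / (r - 1), index=zmatrix.z.index, name="extreme_proportion")


def edge_subset(zmatrix: ZMatrix, mode: str, roi: str = HIPPOCAMPUS) -> np.ndarray:
    """Flatten a Z matrix to the analysed edges.

    ``whole_brain``: strictly lower-triangular entries (each undirected edge
    once, r*(r-1)/2 values); ``hippocampus``: the 22 edges incident to the
    hippocampus (``roi`` row, diagonal excluded).
    """
    z = zmatrix.z.to_numpy()
    if mode == "whole_brain":
        return z[np.tril_indices(z.shape[0], k=-1)]
    if mode == "hippocampus":
        if roi not in zmatrix.z.index:
            raise KeyError(f"ROI {roi!r} not in the Z matrix")
        row = zmatrix.z.loc[roi].drop(index=roi)
        return row.to_numpy()
    raise ValueError(f"unknown edge-subset mode {mode!r}; use 'whole_brain' or 'hippocampus'")


def zmatrices_to_long(zmatrices: list[ZMatrix], groups: pd.Series | dict) -> pd.DataFrame:
    """Tidy per-edge table (participant, group, roi_i, roi_j, z, p_edge) over
    the unique lower-triangular edges."""
    lookup = groups if isinstance(groups, dict) else groups.to_dict()
    frames = []
    for zm in zmatrices:
        rois = list(zm.z.columns)
        ii, jj = np.tril_indices(len(rois), k=-1)
        zvals = zm.z.to_numpy()[ii, jj]
        frames.append(pd.DataFrame({
            "participant_id": zm.participant_id,
            "group": lookup[zm.participant_id],
            "roi_i": [rois[a] for a in ii],
            "roi_j": [rois[b] for b in jj],
            "z": zvals,
            "p_edge": 2.0 * sps.norm.sf(np.abs(zvals)),
        }))
    return pd.concat(frames, ignore_index=True)
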