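"""Synthetic cohorts with the statistical structure the analysis assumes.

Generates demographics matching the study sample (three groups: healthy
controls, clinical high-risk, first-episode psychosis), group-specific
multivariate-normal regional V_T tables with configurable covariance
shrinkage in the patient groups, a smooth peaked arterial input function and
2TCM-driven time-activity curves, so every downstream stage is testable
without any acquired data.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig, FrameSchedule, InputFunction
from .kinetics import KineticParams, solve_2tcm_forward

__all__ = [
    "simulate_demographics",
    "shrink_covariance",
    "simulate_regional_binding",
    "simulate_input_function",
    "simulate_tac",
    "simulate_cohort",
]

# symptom-score generator settings (mean, SD) per group: Hamilton anxiety and
# depression scales, truncated at 0
_HAM_A = {"HC": (3.8, 2.7), "CHRp": (17.6, 10.1), "FEP": (10.8, 6.3)}
_HAM_D = {"HC": (2.4, 1.8), "CHRp": (12.5, 6.4), "FEP": (8.8, 4.8)}
# chlorpromazine-equivalent antipsychotic dose in medicated FEP participants
_CPZ_MEAN_SD = (204.3, 141.9)
_CPZ_MEDICATED_FRACTION = 0.7

_AGE_RANGE = (18.0, 40.0)


def simulate_demographics(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """One row per participant: id, group, age, sex and symptom scores.

    Age is drawn Normal(group mean, group SD) truncated to the study's 18-40
    range by redraw; sex is Bernoulli with the group's female proportion.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for group, n in config.n_per_group.items():
        mu, sd = config.age_mean_sd_per_group[group]
        p_female = config.sex_prob_per_group[group]
        for i in range(n):
            age = rng.normal(mu, sd)
            while not _AGE_RANGE[0] <= age <= _AGE_RANGE[1]:
                age = rng.normal(mu, sd)
            sex = "F" if rng.random() < p_female else "M"
            ham_a = max(0.0, rng.normal(*_HAM_A.get(group, (0.0, 1.0))))
            ham_d = max(0.0, rng.normal(*_HAM_D.get(group, (0.0, 1.0))))
            cpz = 0.0
            if group == "FEP" and rng.random() < _CPZ_MEDICATED_FRACTION:
                cpz = max(0.0, rng.normal(*_CPZ_MEAN_SD))
            rows.append({
                "participant_id": f"{group}{i + 1:02d}",
                "group": group,
                "age": round(float(age), 2),
                "sex": sex,
                "ham_a": round(float(ham_a), 1),
                "ham_d": round(float(ham_d), 1),
                "cpz_mg": round(float(cpz), 1),
            })
    return pd.DataFrame(rows)


def shrink_covariance(sigma: np.ndarray, lam: float) -> np.ndarray:
    """Shrink off-diagonal covariance toward independence:
    sigma' = (1 - lam)*sigma + lam*diag(sigma).

    Diagonal is unchanged, off-diagonals scale by (1 - lam); a convex
    combination of PSD matrices, so positive semi-definiteness is preserved.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"shrinkage lambda must be in [0, 1], got {lam}")
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1] or not np.allclose(sigma, sigma.T):
        raise ValueError("sigma must be a symmetric square matrix")
    return (1.0 - lam) * sigma + lam * np.diag(np.diag(sigma))


def simulate_regional_binding(
    config: CohortConfig,
    demographics: pd.DataFrame,
    seed: int | None = None,
) -> pd.DataFrame:
    """Participants x ROI table of V_T (mL/cm^3).

    Per group, rows are drawn from MVN(mean_vt, shrink(base_covariance,
    lambda_group)); rows with any non-positive value are redrawn.  Linear
    age/sex effects (zero by default) are added afterwards.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    r = len(config.roi_names)
    out = np.empty((len(demographics), r))
    age_ref = float(demographics["age"].mean())
    for group in config.n_per_group:
        idx = np.flatnonzero((demographics["group"] == group).to_numpy())
        if idx.size == 0:
            continue
        cov = shrink_covariance(config.base_covariance, config.shrinkage_per_group[group])
        draws = rng.multivariate_normal(config.mean_vt, cov, size=idx.size, method="cholesky")
        for i in range(idx.size):
            tries = 0
            while np.any(draws[i] <= 0):
                draws[i] = rng.multivariate_normal(config.mean_vt, cov, method="cholesky")
                tries += 1
                if tries > 1000:
                    raise RuntimeError("cannot draw positive V_T; check mean/covariance scale")
        out[idx] = draws
    sex01 = (demographics["sex"] == "M").to_numpy(dtype=float)
    out += np.outer(demographics["age"].to_numpy() - age_ref, config.age_effect)
    out += np.outer(sex01, config.sex_effect)
    if np.any(out <= 0):
        raise RuntimeError("age/sex effects pushed V_T non-positive; reduce effect sizes")
    return pd.DataFrame(out, index=demographics["participant_id"].to_numpy(), columns=list(config.roi_names)).rename_axis("participant_id")


def simulate_input_function(
    schedule: FrameSchedule,
    peak_time_min: float = 1.0,
    peak_value_kbq_ml: float = 80.0,
    decay_rates_per_min: tuple[float, ...] = (4.0, 0.5, 0.02),
    amplitudes: tuple[float, ...] | None = None,
    plasma_to_blood_ratio: float = 1.25,
    dt_s: float = 1.0,
    pad_min: float = 0.5,
) -> InputFunction:
    """Smooth, peaked arterial input: linear rise to a single early peak then
    a tri-exponential (Feng-type) decay of the parent plasma activity; the
    whole-blood curve is parent / ``plasma_to_blood_ratio``.
    """
    if peak_time_min <= 0 or peak_value_kbq_ml < 0 or plasma_to_blood_ratio <= 0:
        raise ValueError("peak time, peak value and plasma-to-blood ratio must be positive")
    rates = np.asarray(decay_rates_per_min, dtype=float)
    if np.any(rates < 0):
        raise ValueError("decay rates must be non-negative")
    if amplitudes is None:
        amplitudes = tuple(np.geomspace(1.0, 0.1, rates.size)) if rates.size > 1 else (1.0,)
    amp = np.asarray(amplitudes, dtype=float)
    if amp.shape != rates.shape or np.any(amp < 0) or amp.sum() == 0:
        raise ValueError("amplitudes must be non-negative, match decay rates, and not all be zero")
    amp = amp / amp.sum()  # continuous at the peak

    end_min = schedule.end_s / 60.0 + pad_min
    n = int(np.ceil(end_min / (dt_s / 60.0)))
    t = np.arange(n + 1) * (dt_s / 60.0)
    rise = peak_value_kbq_ml * t / peak_time_min
    tail = peak_value_kbq_ml * (amp[None, :] * np.exp(-np.outer(t - peak_time_min, rates))).sum(axis=1)
    parent = np.where(t <= peak_time_min, rise, tail)
    return InputFunction(t, parent, parent / plasma_to_blood_ratio)


def simulate_tac(
    params: KineticParams,
    input_function: InputFunction,
    schedule: FrameSchedule,
    noise_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
    duration_weighted: bool = False,
) -> np.ndarray:
    """Frame-averaged 2TCM forward TAC plus proportional Gaussian frame noise.

    Noise SD is ``noise_fraction`` times the frame value; with
    ``duration_weighted`` the SD additionally scales with 1/sqrt(frame
    duration / mean duration).  ``noise_fraction=0`` returns the exact model
    curve.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    clean = solve_2tcm_forward(params, input_function, schedule)
    if noise_fraction == 0.0:
        return clean
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = noise_fraction * np.abs(clean)
    if duration_weighted:
        d = schedule.frame_duration_s
        sd = sd / np.sqrt(d / d.mean())
    return clean + rng.normal(0.0, 1.0, clean.shape) * sd


def simulate_cohort(config: CohortConfig, seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: (participants, V_T table) from one config and seed."""
    base = config.seed if seed is None else seed
    demo = simulate_demographics(config, seed=base)
    vt = simulate_regional_binding(config, demo, seed=base + 1)
    return demo, vt
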