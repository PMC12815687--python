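"""Configuration objects shared across the pipeline.

Holds the cohort description used by the synthetic-data generator, the PET
frame schedule, and the arterial input-function container.  All containers
are plain dataclasses that validate on construction and round-trip through
YAML / plain dicts so that a whole run is reproducible from one config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ROI_NAMES",
    "HIPPOCAMPUS",
    "GROUPS",
    "FrameSchedule",
    "InputFunction",
    "CohortConfig",
    "default_cohort_config",
]

#: The 23 regions of interest quantified by the pipeline, in canonical order.
ROI_NAMES: tuple[str, ...] = (
    "whole_brain",
    "whole_brain_grey_matter",
    "cortex",
    "subcortical_regions",
    "cerebellum",
    "brain_stem",
    "occipital_lobe",
    "insular_cortex",
    "temporal_lobe",
    "frontal_lobe",
    "cingulate_cortex",
    "parietal_lobe",
    "basal_ganglia",
    "thalamus",
    "parahippocampal_gyrus",
    "amygdala",
    "hippocampus",
    "anterior_cingulate_cortex",
    "globus_pallidus",
    "striatum",
    "caudate",
    "nucleus_accumbens",
    "putamen",
)

HIPPOCAMPUS = "hippocampus"

#: Allowed participant group labels: healthy controls, clinical high-risk
#: for psychosis, first-episode psychosis.
GROUPS: tuple[str, ...] = ("HC", "CHRp", "FEP")


@dataclass(frozen=True)
class FrameSchedule:
    """Dynamic PET frame binning: start and duration of each frame, seconds.

    Frames must be contiguous (each frame starts where the previous one
    ends) with strictly positive durations.
    """

    frame_start_s: np.ndarray
    frame_duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start_s, dtype=float)
        dur = np.asarray(self.frame_duration_s, dtype=float)
        object.__setattr__(self, "frame_start_s", start)
        object.__setattr__(self, "frame_duration_s", dur)
        if start.ndim != 1 or start.shape != dur.shape or start.size == 0:
            raise ValueError("frame_start_s and frame_duration_s must be equal-length 1-D arrays")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous")

    @property
    def n_frames(self) -> int:
        return int(self.frame_start_s.size)

    @property
    def frame_end_s(self) -> np.ndarray:
        return self.frame_start_s + self.frame_duration_s

    @property
    def end_s(self) -> float:
        return float(self.frame_end_s[-1])

    @property
    def mid_min(self) -> np.ndarray:
        """Frame midpoints in minutes."""
        return (self.frame_start_s + 0.5 * self.frame_duration_s) / 60.0

    @classmethod
    def default(cls) -> "FrameSchedule":
        """70.5-minute dynamic acquisition: 15 s x 10, 60 s x 3, 120 s x 5, 300 s x 11."""
        dur = np.concatenate([
            np.full(10, 15.0),
            np.full(3, 60.0),
            np.full(5, 120.0),
            np.full(11, 300.0),
        ])
        start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(start, dur)


@dataclass(frozen=True)
class InputFunction:
    """Arterial input: metabolite-corrected parent plasma and whole blood.

    ``sample_times_min`` must be strictly increasing and start at 0;
    activities are kBq/mL and must be non-negative.
    """

    sample_times_min: np.ndarray
    plasma_activity: np.ndarray
    wholeblood_activity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times_min, dtype=float)
        cp = np.asarray(self.plasma_activity, dtype=float)
        cb = np.asarray(self.wholeblood_activity, dtype=float)
        object.__setattr__(self, "sample_times_min", t)
        object.__setattr__(self, "plasma_activity", cp)
        object.__setattr__(self, "wholeblood_activity", cb)
        if not (t.shape == cp.shape == cb.shape) or t.ndim != 1 or t.size < 2:
            raise ValueError("input-function arrays must be equal-length 1-D with >= 2 samples")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("sample times must start at 0 and be strictly increasing")
        if np.any(cp < 0) or np.any(cb < 0):
            raise ValueError("activities must be non-negative")

    @property
    def end_min(self) -> float:
        return float(self.sample_times_min[-1])


def _as_group_map(value: Mapping[str, float], name: str) -> dict[str, float]:
    bad = set(value) - set(GROUPS)
    if bad:
        raise ValueError(f"{name}: unknown group labels {sorted(bad)}; allowed {list(GROUPS)}")
    return dict(value)


@dataclass
class CohortConfig:
    """Everything the synthetic cohort generator needs.

    ``mean_vt`` and ``base_covariance`` define the healthy-control V_T
    distribution (mL/cm^3); patient groups are drawn from the same means with
    the off-diagonal covariance shrunk by ``shrinkage_per_group`` (lambda in
    [0, 1], 0 = identical covariance, 1 = independent regions).  The default
    numbers are synthetic, literature-plausible values, not measured ones.
    """

    n_per_group: dict[str, int]
    roi_names: tuple[str, ...] = ROI_NAMES
    mean_vt: np.ndarray | None = None
    base_covariance: np.ndarray | None = None
    shrinkage_per_group: dict[str, float] = field(default_factory=dict)
    age_mean_sd_per_group: dict[str, tuple[float, float]] = field(default_factory=dict)
    sex_prob_per_group: dict[str, float] = field(default_factory=dict)  # P(female)
    age_effect: np.ndarray | None = None  # V_T change per year, per ROI
    sex_effect: np.ndarray | None = None  # V_T shift for males, per ROI
    noise_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_per_group = {k: int(v) for k, v in _as_group_map(self.n_per_group, "n_per_group").items()}
        if not self.n_per_group or any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("n_per_group must be non-empty with all counts > 0")
        self.roi_names = tuple(self.roi_names)
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("roi_names must be unique")
        r = len(self.roi_names)
        if self.mean_vt is None:
            self.mean_vt = _default_mean_vt(self.roi_names)
        self.mean_vt = np.asarray(self.mean_vt, dtype=float)
        if self.mean_vt.shape != (r,):
            raise ValueError(f"mean_vt must have length {r}")
        if np.any(self.mean_vt <= 0):
            raise ValueError("mean_vt must be positive")
        if self.base_covariance is None:
            self.base_covariance = _default_covariance(self.mean_vt)
        self.base_covariance = np.asarray(self.base_covariance, dtype=float)
        if self.base_covariance.shape != (r, r):
            raise ValueError(f"base_covariance must be {r}x{r}")
        if not np.allclose(self.base_covariance, self.base_covariance.T):
            raise ValueError("base_covariance must be symmetric")
        eig = np.linalg.eigvalsh(self.base_covariance)
        if eig.min() < -1e-10 * max(eig.max(), 1.0):
            raise ValueError("base_covariance must be positive semi-definite")
        self.shrinkage_per_group = _as_group_map(
            {g: self.shrinkage_per_group.get(g, _DEFAULT_SHRINKAGE.get(g, 0.0)) for g in self.n_per_group},
            "shrinkage_per_group",
        )
        for g, lam in self.shrinkage_per_group.items():
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"shrinkage for {g} must be in [0, 1], got {lam}")
        self.age_mean_sd_per_group = _as_group_map(
            {g: tuple(self.age_mean_sd_per_group.get(g, _DEFAULT_AGE[g])) for g in self.n_per_group},
            "age_mean_sd_per_group",
        )
        self.sex_prob_per_group = _as_group_map(
            {g: float(self.sex_prob_per_group.get(g, _DEFAULT_SEX_PROB[g])) for g in self.n_per_group},
            "sex_prob_per_group",
        )
        for g, p in self.sex_prob_per_group.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"sex probability for {g} must be in [0, 1]")
        self.age_effect = np.zeros(r) if self.age_effect is None else np.asarray(self.age_effect, dtype=float)
        self.sex_effect = np.zeros(r) if self.sex_effect is None else np.asarray(self.sex_effect, dtype=float)
        if self.age_effect.shape != (r,) or self.sex_effect.shape != (r,):
            raise ValueError("age_effect and sex_effect must match the ROI count")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        self.seed = int(self.seed)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_per_group": dict(self.n_per_group),
            "roi_names": list(self.roi_names),
            "mean_vt": self.mean_vt.tolist(),
            "base_covariance": self.base_covariance.tolist(),
            "shrinkage_per_group": dict(self.shrinkage_per_group),
            "age_mean_sd_per_group": {g: list(v) for g, v in self.age_mean_sd_per_group.items()},
            "sex_prob_per_group": dict(self.sex_prob_per_group),
            "age_effect": self.age_effect.tolist(),
            "sex_effect": self.sex_effect.tolist(),
            "noise_fraction": self.noise_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "age_mean_sd_per_group" in d:
            d["age_mean_sd_per_group"] = {g: tuple(v) for g, v in d["age_mean_sd_per_group"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# Demographics of the study sample the generator emulates: age mean (SD)
# and female proportion per group.
_DEFAULT_AGE = {"HC": (25.1, 4.5), "CHRp": (25.1, 4.6), "FEP": (29.0, 3.6)}
_DEFAULT_SEX_PROB = {"HC": 14 / 23, "CHRp": 15 / 22, "FEP": 3 / 10}
# Graded covariance reduction in patient groups (healthy controls define the
# reference covariance).
_DEFAULT_SHRINKAGE = {"HC": 0.0, "CHRp": 0.15, "FEP": 0.35}

# Synthetic per-ROI mean V_T (mL/cm^3).  NOT measured values: chosen to be
# plausible for a benzodiazepine-site tracer with predominantly limbic
# binding (hippocampus largest, brain stem / pallidus smallest).
_SYNTHETIC_MEAN_VT = {
    "whole_brain": 3.5,
    "whole_brain_grey_matter": 4.0,
    "cortex": 4.0,
    "subcortical_regions": 3.2,
    "cerebellum": 2.0,
    "brain_stem": 1.6,
    "occipital_lobe": 3.6,
    "insular_cortex": 4.6,
    "temporal_lobe": 4.4,
    "frontal_lobe": 4.2,
    "cingulate_cortex": 4.5,
    "parietal_lobe": 4.0,
    "basal_ganglia": 2.8,
    "thalamus": 2.4,
    "parahippocampal_gyrus": 5.0,
    "amygdala": 5.2,
    "hippocampus": 6.0,
    "anterior_cingulate_cortex": 4.6,
    "globus_pallidus": 1.8,
    "striatum": 3.0,
    "caudate": 3.2,
    "nucleus_accumbens": 4.8,
    "putamen": 2.9,
}

#: Uniform inter-regional correlation of the synthetic healthy covariance.
#: Between-subject regional V_T values covary strongly (shared plasma
#: clearance and tracer delivery; several ROIs are overlapping composites of
#: others), so the healthy default sits at the upper end of the realistic
#: 0.7-0.9 range.
_DEFAULT_RHO = 0.8
#: Between-subject coefficient of variation of regional V_T.
_DEFAULT_CV = 0.12


def _default_mean_vt(roi_names: Sequence[str]) -> np.ndarray:
    try:
        return np.array([_SYNTHETIC_MEAN_VT[r] for r in roi_names], dtype=float)
    except KeyError:
        # custom ROI sets fall back to a flat plausible value
        return np.full(len(roi_names), 3.5)


def _default_covariance(mean_vt: np.ndarray, rho: float = _DEFAULT_RHO, cv: float = _DEFAULT_CV) -> np.ndarray:
    sd = cv * np.asarray(mean_vt, dtype=float)
    corr = np.full((sd.size, sd.size), rho)
    np.fill_diagonal(corr, 1.0)
    return corr * np.outer(sd, sd)


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """The study-sized default cohort: HC n=23, CHRp n=22, FEP n=10."""
    kwargs = dict(n_per_group={"HC": 23, "CHRp": 22, "FEP": 10}, seed=seed)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)
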