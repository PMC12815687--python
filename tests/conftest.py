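import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import petcovnet as pcn

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def schedule() -> pcn.FrameSchedule:
    return pcn.FrameSchedule.default()


@pytest.fixture(scope="session")
def input_function(schedule) -> pcn.InputFunction:
    return pcn.simulate_input_function(schedule)


@pytest.fixture(scope="session")
def reference_params() -> pcn.KineticParams:
    # V_T = (0.1/0.2)*(1 + 0.05/0.04) = 1.125
    return pcn.KineticParams(K1=0.1, k2=0.2, k3=0.05, k4=0.04, Vb=0.05)


SMALL_ROIS = (
    "hippocampus",
    "amygdala",
    "thalamus",
    "frontal_lobe",
    "temporal_lobe",
    "cerebellum",
    "striatum",
    "nucleus_accumbens",
)


@pytest.fixture(scope="session")
def small_config() -> pcn.CohortConfig:
    """A reduced cohort (8 ROIs) that keeps every pipeline stage fast."""
    return pcn.default_cohort_config(
        seed=7,
        n_per_group={"HC": 12, "CHRp": 8, "FEP": 6},
        roi_names=SMALL_ROIS,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> tuple[pd.DataFrame, pd.DataFrame]:
    return pcn.simulate_cohort(small_config)


def paper_design_cohort(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full study-sized cohort: 23 HC / 22 CHRp / 10 FEP x 23 ROIs."""
    return pcn.simulate_cohort(pcn.default_cohort_config(seed=seed))


@pytest.fixture(scope="session")
def study_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    return paper_design_cohort(seed=11)


def rng_matrix(n: int, r: int, seed: int) -> np.ndarray:
    return np.random.default_rng(seed).normal(size=(n, r))
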