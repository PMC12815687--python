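"""Two-tissue compartment model (2TCM): forward solution and TAC fitting.

The model describes radiotracer exchange between arterial plasma (Cp), a
free/non-specific tissue compartment (C1) and a specifically bound
compartment (C2):

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2

with K1 in mL/cm^3/min and k2..k4 in 1/min.  The measured PET signal mixes
tissue and blood through the fractional blood volume Vb:

    C_pet(t) = (1 - Vb) * (C1(t) + C2(t)) + Vb * C_wholeblood(t)

and each frame value is the time average of C_pet over the frame.  The
macro-parameter of interest is the total volume of distribution

    V_T = (K1/k2) * (1 + k3/k4),

the equilibrium tissue-to-plasma concentration ratio.

The tissue response to a plasma impulse is a sum of two exponentials with
rates alpha_1,2 = ((a -/+ sqrt(a^2 - 4 k2 k4)) / 2), a = k2 + k3 + k4.  For a
piecewise-linear input (how measured input functions are represented) the
convolution has a closed form per segment, evaluated here as a linear
recursion, so the forward curve is exact up to the input interpolation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, signal

from .config import FrameSchedule, InputFunction

__all__ = [
    "KineticParams",
    "FitResult",
    "compute_vt",
    "solve_2tcm_curve",
    "solve_2tcm_forward",
    "fit_2tcm",
    "kinetic_params_for_vt",
    "DEFAULT_BOUNDS",
]


def compute_vt(K1: float, k2: float, k3: float, k4: float) -> float:
    """Total volume of distribution V_T = (K1/k2)(1 + k3/k4)."""
    if k2 <= 0 or k4 <= 0:
        raise ValueError("V_T requires k2 > 0 and k4 > 0")
    return (K1 / k2) * (1.0 + k3 / k4)


@dataclass(frozen=True)
class KineticParams:
    """2TCM rate constants plus fractional blood volume."""

    K1: float  # mL/cm^3/min
    k2: float  # 1/min
    k3: float  # 1/min
    k4: float  # 1/min
    Vb: float = 0.0  # unitless, in [0, 1)

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.Vb < 1.0:
            raise ValueError("Vb must be in [0, 1)")

    @property
    def vt(self) -> float:
        return compute_vt(self.K1, self.k2, self.k3, self.k4)

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.k4, self.Vb])


@dataclass
class FitResult:
    """Outcome of a 2TCM fit: best restart's parameters and diagnostics."""

    params: KineticParams
    rss: float
    converged: bool
    degenerate: bool = False
    n_restarts_used: int = 0
    message: str = ""
    param_se: np.ndarray | None = field(default=None, repr=False)

    @property
    def vt(self) -> float:
        if self.degenerate or self.params.k2 <= 0 or self.params.k4 <= 0:
            return 0.0 if self.params.K1 == 0 else float("nan")
        return self.params.vt


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _exp_conv(alpha: float, cp: np.ndarray, dt: float) -> np.ndarray:
    """Exact convolution exp(-alpha*t) * cp for piecewise-linear cp on a
    uniform grid of spacing dt.  Returns values at the grid points."""
    c0 = cp[:-1]
    m = (cp[1:] - c0) / dt
    if alpha < 1e-12:
        seg = dt * (c0 + cp[1:]) / 2.0
        y = np.concatenate([[0.0], np.cumsum(seg)])
        return y
    e = np.exp(-alpha * dt)
    g = (1.0 - e) / alpha
    seg = c0 * g + m * (dt - g) / alpha
    y = np.empty_like(cp)
    y[0] = 0.0
    # y[i+1] = e*y[i] + seg[i]
    y[1:] = signal.lfilter([1.0], [1.0, -e], seg)
    return y


def _tissue_rates(k2: float, k3: float, k4: float) -> tuple[float, float]:
    a = k2 + k3 + k4
    disc = a * a - 4.0 * k2 * k4
    # cannot be negative for non-negative rates: (k2-k4)^2 + k3*(...) >= 0
    assert disc >= -1e-12 * max(a * a, 1.0), "negative 2TCM discriminant"
    delta = np.sqrt(max(disc, 0.0))
    # floor the root separation to avoid catastrophic cancellation at a
    # (measure-zero) double root; relative error ~1e-8
    delta = max(delta, 1e-8 * max(a, 1e-8))
    alpha1 = (a - delta) / 2.0
    alpha2 = (a + delta) / 2.0
    return alpha1, alpha2


def _grid(input_function: InputFunction, end_min: float, dt_s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if input_function.end_min + 1e-9 < end_min:
        raise ValueError(
            f"input function ends at {input_function.end_min:.2f} min but the "
            f"schedule requires {end_min:.2f} min"
        )
    dt = dt_s / 60.0
    n = int(round(end_min / dt))
    t = np.arange(n + 1) * dt
    cp = np.interp(t, input_function.sample_times_min, input_function.plasma_activity)
    cb = np.interp(t, input_function.sample_times_min, input_function.wholeblood_activity)
    return t, cp, cb


def solve_2tcm_curve(
    params: KineticParams,
    input_function: InputFunction,
    end_min: float,
    dt_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous-time model PET signal on a uniform grid (minutes, kBq/mL)."""
    t, cp, cb = _grid(input_function, end_min, dt_s)
    dt = t[1] - t[0]
    if params.K1 == 0.0:
        tissue = np.zeros_like(t)
    else:
        alpha1, alpha2 = _tissue_rates(params.k2, params.k3, params.k4)
        delta = alpha2 - alpha1
        a1 = params.K1 * (params.k3 + params.k4 - alpha1) / delta
        a2 = params.K1 * (alpha2 - params.k3 - params.k4) / delta
        tissue = a1 * _exp_conv(alpha1, cp, dt) + a2 * _exp_conv(alpha2, cp, dt)
    pet = (1.0 - params.Vb) * tissue + params.Vb * cb
    return t, pet


def _frame_average(t: np.ndarray, y: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Time-average y over each frame via the cumulative trapezoid integral."""
    cum = np.concatenate([[0.0], np.cumsum((y[1:] + y[:-1]) / 2.0 * np.diff(t))])
    start_min = schedule.frame_start_s / 60.0
    end_min = schedule.frame_end_s / 60.0
    i0 = np.interp(start_min, t, cum)
    i1 = np.interp(end_min, t, cum)
    return (i1 - i0) / (end_min - start_min)


def solve_2tcm_forward(
    params: KineticParams,
    input_function: InputFunction,
    schedule: FrameSchedule,
    dt_s: float = 1.0,
) -> np.ndarray:
    """Frame-averaged model TAC (kBq/mL), one value per frame."""
    t, pet = solve_2tcm_curve(params, input_function, schedule.end_s / 60.0, dt_s)
    return _frame_average(t, pet, schedule)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

#: conventional PET bounds for (K1, k2, k3, k4, Vb)
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = (
    (1e-4, 2.0),
    (1e-4, 2.0),
    (1e-4, 2.0),
    (1e-4, 2.0),
    (0.0, 0.2),
)

# fixed multi-start grid spanning decade ranges of the fast rates
_START_GRID: tuple[tuple[float, float, float, float, float], ...] = tuple(
    (K1, k2, k3, 0.05, 0.05)
    for K1, k2, k3 in itertools.product((0.05, 0.5), (0.05, 0.5), (0.03, 0.3))
)


def _frame_weights(schedule: FrameSchedule, weights: str | np.ndarray) -> np.ndarray:
    if isinstance(weights, str):
        if weights == "uniform":
            return np.ones(schedule.n_frames)
        if weights == "duration":
            d = schedule.frame_duration_s
            return np.sqrt(d / d.mean())
        raise ValueError(f"unknown weights mode {weights!r}; use 'uniform' or 'duration'")
    w = np.asarray(weights, dtype=float)
    if w.shape != (schedule.n_frames,):
        raise ValueError("weights must have one entry per frame")
    return w


def fit_2tcm(
    tac: np.ndarray,
    input_function: InputFunction,
    schedule: FrameSchedule,
    weights: str | np.ndarray = "uniform",
    n_restarts: int = 8,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
    dt_s: float = 1.0,
) -> FitResult:
    """Weighted bounded least squares of the 2TCM against a measured TAC.

    Runs a fixed multi-start grid (plus deterministic log-uniform extras when
    ``n_restarts`` exceeds the grid) and returns the best restart.  A fit is
    never silently dropped: non-convergence is flagged on the result.
    """
    tac = np.asarray(tac, dtype=float)
    if tac.shape != (schedule.n_frames,):
        raise ValueError("TAC length must match the schedule")
    if schedule.n_frames < 6:
        raise ValueError("need at least 6 frames to fit the 2TCM")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    w = _frame_weights(schedule, weights)

    # degenerate data: nothing was injected / measured
    if np.max(np.abs(tac)) == 0.0 and np.max(input_function.plasma_activity) == 0.0:
        params = KineticParams(0.0, 1e-4, 1e-4, 1e-4, 0.0)
        return FitResult(params, 0.0, converged=True, degenerate=True,
                         message="all-zero TAC and input; parameters undetermined")

    t, cp, cb = _grid(input_function, schedule.end_s / 60.0, dt_s)
    dt = t[1] - t[0]

    def model(x: np.ndarray) -> np.ndarray:
        K1, k2, k3, k4, Vb = x
        alpha1, alpha2 = _tissue_rates(k2, k3, k4)
        delta = alpha2 - alpha1
        a1 = K1 * (k3 + k4 - alpha1) / delta
        a2 = K1 * (alpha2 - k3 - k4) / delta
        tissue = a1 * _exp_conv(alpha1, cp, dt) + a2 * _exp_conv(alpha2, cp, dt)
        pet = (1.0 - Vb) * tissue + Vb * cb
        return _frame_average(t, pet, schedule)

    def residuals(x: np.ndarray) -> np.ndarray:
        return w * (model(x) - tac)

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = list(_START_GRID[: n_restarts])
    if n_restarts > len(_START_GRID):
        rng = np.random.default_rng(0)
        extra = n_restarts - len(_START_GRID)
        starts += [tuple(np.exp(rng.uniform(np.log(np.maximum(lo, 1e-4)), np.log(hi))))
                   for _ in range(extra)]

    best = None
    any_converged = False
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        try:
            res = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception:  # noqa: BLE001 - a failed restart is recorded, not fatal
            continue
        ok = res.success and np.all(np.isfinite(res.x))
        any_converged = any_converged or ok
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        params = KineticParams(0.0, 1e-4, 1e-4, 1e-4, 0.0)
        return FitResult(params, float("inf"), converged=False, degenerate=True,
                         n_restarts_used=len(starts), message="all restarts failed")

    K1, k2, k3, k4, Vb = best.x
    params = KineticParams(float(K1), float(k2), float(k3), float(k4), float(Vb))
    rss = float(2.0 * best.cost)
    se = None
    try:
        jtj = best.jac.T @ best.jac
        dof = max(schedule.n_frames - 5, 1)
        cov = np.linalg.inv(jtj) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        pass
    degenerate = np.max(np.abs(tac)) == 0.0
    msg = "" if any_converged else "no restart reported convergence; best restart returned"
    return FitResult(params, rss, converged=any_converged, degenerate=degenerate,
                     n_restarts_used=len(starts), message=msg, param_se=se)


def kinetic_params_for_vt(
    vt: float,
    K1: float = 0.35,
    k3: float = 0.05,
    k4: float = 0.04,
    Vb: float = 0.05,
) -> KineticParams:
    """Rate constants consistent with a target V_T (used to drive TAC
    simulation from a sampled binding table): k2 = K1*(1 + k3/k4)/V_T."""
    if vt <= 0:
        raise ValueError("V_T must be positive")
    k2 = K1 * (1.0 + k3 / k4) / vt
    return KineticParams(K1, k2, k3, k4, Vb)
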