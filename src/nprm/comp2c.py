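"""Two-tissue-compartment reference model with fractional blood volume and delay.

The impulse response of the (K1, k2, k3, k4) system is

    h(t) = K1 [(k3 + k4 - a1) e^{-a1 t} + (a2 - k3 - k4) e^{-a2 t}] / (a2 - a1),

with a1, a2 the roots of s^2 + (k2+k3+k4) s + k2 k4; the modeled tissue
curve is Vb * Cb(t - delay) + (h * Cp)(t - delay), frame-averaged.  The
whole-blood input serves as both Cb and Cp here.  Adding a sharp (fast
transit) vascular element to h yields an extended residue whose
decomposition gives the same parameter set as the nonparametric route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .basis import _ConvolutionEngine
from .frames import SEC_PER_MIN, FitWeights, FrameSchedule, InputFunction
from .residue import DEFAULT_T_STAR_S, Residue

__all__ = ["TwoCParams", "model_2c_curve", "fit_2c", "residue_2c"]

# multistart sampling ranges (log-uniform, jittered)
_START_RANGES = {
    "K1": (0.01, 1.0),
    "k2": (0.01, 1.0),
    "k3": (1e-4, 0.2),
    "k4": (1e-5, 0.05),
    "Vb_frac": (1e-4, 0.3),
}


@dataclass(frozen=True)
class TwoCParams:
    K1: float  # mL/min/g
    k2: float  # 1/min
    k3: float  # 1/min
    k4: float  # 1/min
    Vb_frac: float  # mL/mL
    delay_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4", "Vb_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def flux(self) -> float:
        """Asymptotic net influx K1 k3 / (k2 + k3) (exact when k4 = 0)."""
        denom = self.k2 + self.k3
        return self.K1 * self.k3 / denom if denom > 0 else 0.0


def impulse_response(params: TwoCParams, t_s: np.ndarray) -> np.ndarray:
    """h(t) in mL/min/g on a time grid in seconds (rates are per minute)."""
    t = np.asarray(t_s, dtype=float) / SEC_PER_MIN
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    disc = max(s * s - 4.0 * k2 * k4, 0.0)
    root = np.sqrt(disc)
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    if a2 - a1 < 1e-9:
        # repeated-root limit: h = K1 e^{-a t} (1 + (k3 + k4 - a) t)
        return K1 * np.exp(-a1 * t) * (1.0 + (k3 + k4 - a1) * t)
    return (
        K1
        * ((k3 + k4 - a1) * np.exp(-a1 * t) + (a2 - k3 - k4) * np.exp(-a2 * t))
        / (a2 - a1)
    )


def model_2c_curve(
    params: TwoCParams,
    aif: InputFunction,
    schedule: FrameSchedule,
    fine_dt_s: float = 1.0,
    _engine: _ConvolutionEngine | None = None,
) -> np.ndarray:
    """Frame-averaged model tissue curve for the given parameters."""
    engine = _engine or _ConvolutionEngine(schedule, aif, fine_dt_s)
    t = engine.binner.node_t
    h = impulse_response(params, t - t[0])
    tissue = engine.convolve(h, params.delay_s)[:, 0]
    blood = params.Vb_frac * aif(t - params.delay_s)
    return engine.frame_average(tissue + blood)[:, 0]


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(p: np.ndarray) -> np.ndarray:
    p = np.maximum(np.asarray(p, dtype=float), 1e-12)
    return p + np.log(-np.expm1(-p))


def _theta_to_params(theta: np.ndarray, delay_s: float) -> TwoCParams:
    K1, k2, k3, k4, Vb = _softplus(theta)
    return TwoCParams(K1, k2, k3, k4, Vb, delay_s)


def fit_2c(
    tac: np.ndarray,
    aif: InputFunction,
    schedule: FrameSchedule,
    weights: FitWeights,
    n_starts: int = 10,
    delay_grid_s: np.ndarray | None = None,
    seed: int = 0,
    fine_dt_s: float = 1.0,
    maxiter: int = 500,
) -> tuple[TwoCParams, float]:
    """Weighted least-squares fit of the 2C model.

    Rate constants and the blood fraction are kept nonnegative through a
    softplus parameterization optimized by a quasi-Newton (BFGS-family)
    method; the delay is profiled on a grid, then a seeded multistart is
    run at the best delay and the lowest-misfit solution wins.
    Deterministic for a given seed.
    """
    tac = np.asarray(tac, dtype=float)
    w = weights.w
    if not np.any(tac != 0.0):
        return TwoCParams(0.0, 0.0, 0.0, 0.0, 0.0, 0.0), 0.0
    if delay_grid_s is None:
        delay_grid_s = np.array([0.0])
    delay_grid_s = np.atleast_1d(np.asarray(delay_grid_s, dtype=float))
    engine = _ConvolutionEngine(schedule, aif, fine_dt_s)

    def objective(theta: np.ndarray, delay: float) -> float:
        try:
            pred = model_2c_curve(
                _theta_to_params(theta, delay), aif, schedule, fine_dt_s, _engine=engine
            )
        except (ValueError, FloatingPointError):
            return 1e30
        return float(np.sum(w * (tac - pred) ** 2))

    def local_fit(theta0: np.ndarray, delay: float):
        res = minimize(
            objective,
            theta0,
            args=(delay,),
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": 1e-8},
        )
        return res.x, float(res.fun)

    default_start = _softplus_inv([0.1, 0.1, 0.01, 0.001, 0.05])
    # profile the delay with the default start
    best_delay = None
    for d in delay_grid_s:
        x, f = local_fit(default_start, float(d))
        if best_delay is None or f < best_delay[2]:
            best_delay = (x, float(d), f)
    x_best, delay, f_best = best_delay

    rng = np.random.default_rng(seed)
    names = ("K1", "k2", "k3", "k4", "Vb_frac")
    for _ in range(max(0, n_starts - 1)):
        p0 = [
            np.exp(rng.uniform(np.log(_START_RANGES[n][0]), np.log(_START_RANGES[n][1])))
            for n in names
        ]
        x, f = local_fit(_softplus_inv(p0), delay)
        if f < f_best:
            x_best, f_best = x, f
    return _theta_to_params(x_best, delay), f_best


def residue_2c(
    params: TwoCParams,
    t_star_s: float = DEFAULT_T_STAR_S,
    T_end_s: float = 3900.0,
    vascular_shape: str = "triangle",
) -> Residue:
    """Extended residue: sharp vascular element plus the 2C impulse response.

    The vascular element has area Vb_frac and mean transit t*/2; a triangle
    (default) falls linearly to zero at t*, the rectangle alternative is
    constant on [0, t*/...] with matching area and mean transit.
    """
    grid = np.union1d(
        np.arange(0.0, min(60.0, T_end_s) + 1e-9, 1.0),
        np.arange(60.0, T_end_s + 1e-9, 10.0),
    )
    grid = np.union1d(grid, [t_star_s, T_end_s])
    if vascular_shape == "rectangle":
        # a knot just below t* keeps the step sharp under linear interpolation
        grid = np.union1d(grid, [t_star_s - 1e-6])
    h = impulse_response(params, grid)
    t_star_min = t_star_s / SEC_PER_MIN
    if vascular_shape == "triangle":
        height = 2.0 * params.Vb_frac / t_star_min
        vasc = height * np.clip(1.0 - grid / t_star_s, 0.0, None)
    elif vascular_shape == "rectangle":
        height = params.Vb_frac / t_star_min
        vasc = np.where(grid < t_star_s, height, 0.0)
    else:
        raise ValueError(f"unknown vascular_shape: {vascular_shape!r}")
    values = h + vasc
    if np.any(np.diff(values) > 1e-8 * max(values.max(), 1e-300)):
        raise ValueError("vascular element plus impulse response is not nonincreasing")
    return Residue(grid, values)
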