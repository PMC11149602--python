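"""Frame-schedule arithmetic, fit weights, and arterial input functions.

Conventions used throughout the package:

* time is carried in **seconds**; flow-like quantities are per **minute**,
  so time integrals divide by 60 internally;
* activity is decay-corrected kBq/mL;
* a frame schedule is contiguous and non-overlapping, with mid-frame time
  ``start + duration / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "F18_HALFLIFE_MIN",
    "SEC_PER_MIN",
    "FrameSchedule",
    "FitWeights",
    "InputFunction",
    "build_schedule",
    "fit_weights",
    "shift_input",
    "frame_average",
    "FrameBinner",
    "convolve_residue_input",
]

F18_HALFLIFE_MIN = 109.77
SEC_PER_MIN = 60.0


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous acquisition frames with per-frame start and duration."""

    start_s: np.ndarray
    duration_s: np.ndarray
    isotope_halflife_min: float = F18_HALFLIFE_MIN

    def __post_init__(self) -> None:
        start = np.atleast_1d(np.asarray(self.start_s, dtype=float))
        dur = np.atleast_1d(np.asarray(self.duration_s, dtype=float))
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.size == 0 or start.shape != dur.shape:
            raise ValueError("start_s and duration_s must be equal-length, non-empty")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1], atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")
        if self.isotope_halflife_min <= 0:
            raise ValueError("isotope half-life must be positive")

    @property
    def J(self) -> int:
        return int(self.start_s.size)

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + self.duration_s / 2.0

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def total_duration_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])

    @property
    def decay_lambda_per_s(self) -> float:
        """Decay constant in 1/s; 0 when the half-life is infinite."""
        if np.isinf(self.isotope_halflife_min):
            return 0.0
        return float(np.log(2.0) / (self.isotope_halflife_min * SEC_PER_MIN))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.J),
                "start_s": self.start_s,
                "duration_s": self.duration_s,
            }
        )


def build_schedule(
    spec: list[tuple[int, float]],
    isotope_halflife_min: float = F18_HALFLIFE_MIN,
) -> FrameSchedule:
    """Expand ``[(count, duration_s), ...]`` blocks into a contiguous schedule.

    The schedule starts at t = 0 and the total duration is exactly
    ``sum(count * duration)``.
    """
    if not spec:
        raise ValueError("empty schedule spec")
    durations: list[float] = []
    for count, duration in spec:
        if int(count) < 1:
            raise ValueError(f"block count must be >= 1, got {count}")
        if duration <= 0:
            raise ValueError(f"block duration must be positive, got {duration}")
        durations.extend([float(duration)] * int(count))
    dur = np.asarray(durations)
    start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    return FrameSchedule(start, dur, isotope_halflife_min=isotope_halflife_min)


@dataclass(frozen=True)
class FitWeights:
    """Per-frame nonnegative least-squares weights, normalized to sum 1."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        object.__setattr__(self, "w", w / total)


def fit_weights(schedule: FrameSchedule, convention: str = "inverse") -> FitWeights:
    """Duration- and decay-based frame weights.

    ``convention="inverse"`` (default) takes w_j proportional to
    duration_j * exp(-lambda * mid_j), i.e. the frame duration divided by
    the decay-correction multiplier: late frames carry relatively inflated
    variance after decay correction, so they are down-weighted.
    ``convention="product"`` multiplies by the correction factor instead.
    """
    lam = schedule.decay_lambda_per_s
    if convention == "inverse":
        raw = schedule.duration_s * np.exp(-lam * schedule.mid_s)
    elif convention == "product":
        raw = schedule.duration_s * np.exp(lam * schedule.mid_s)
    else:
        raise ValueError(f"unknown weight convention: {convention!r}")
    return FitWeights(raw)


@dataclass(frozen=True)
class InputFunction:
    """Sampled whole-blood input curve, piecewise-linear in time.

    Evaluation is 0 before the first sample and holds the last sample
    value afterwards.
    """

    sample_times_s: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times_s, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "sample_times_s", t)
        object.__setattr__(self, "activity", a)
        if t.ndim != 1 or t.shape != a.shape or t.size == 0:
            raise ValueError("times and activity must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("activity must be nonnegative")
        if np.any(~np.isfinite(a)):
            raise ValueError("activity must be finite")

    def __call__(self, t) -> np.ndarray:
        return np.interp(
            np.asarray(t, dtype=float),
            self.sample_times_s,
            self.activity,
            left=0.0,
            right=float(self.activity[-1]),
        )

    def shifted(self, delay_s: float) -> "InputFunction":
        return InputFunction(self.sample_times_s + float(delay_s), self.activity)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.sample_times_s, "activity_kBq_ml": self.activity}
        )


def shift_input(aif: InputFunction, delay_s: float) -> InputFunction:
    """Delay the input curve: shifted(t) == original(t - delay_s)."""
    return aif.shifted(delay_s)


def frame_average(curve, schedule: FrameSchedule, fine_dt_s: float = 1.0) -> np.ndarray:
    """Mean of ``curve(t)`` over each frame, via midpoint sampling."""
    if fine_dt_s > schedule.duration_s.min():
        raise ValueError("fine_dt_s must not exceed the shortest frame duration")
    out = np.empty(schedule.J)
    for j, (s, d) in enumerate(zip(schedule.start_s, schedule.duration_s)):
        n = max(1, int(np.ceil(d / fine_dt_s)))
        t = s + (np.arange(n) + 0.5) * (d / n)
        out[j] = float(np.mean(curve(t)))
    return out


class FrameBinner:
    """Fast repeated frame-averaging of curves tabulated on a fine node grid.

    The node grid is ``t_n = start + n * dt``; frame means are taken over
    midpoint samples, with linear interpolation of the tabulated values.
    """

    def __init__(self, schedule: FrameSchedule, fine_dt_s: float = 1.0):
        self.schedule = schedule
        self.dt = float(fine_dt_s)
        t0 = float(schedule.start_s[0])
        total = schedule.total_duration_s
        n_nodes = int(round(total / self.dt)) + 1
        self.node_t = t0 + np.arange(n_nodes) * self.dt
        n_mid = n_nodes - 1
        self.mid_t = t0 + (np.arange(n_mid) + 0.5) * self.dt
        # frame j owns midpoint samples [edges[j], edges[j+1])
        edges = np.round((schedule.start_s - t0) / self.dt).astype(int)
        self.edges = np.append(edges, n_mid)
        self.counts = np.diff(self.edges)
        if np.any(self.counts < 1):
            raise ValueError("fine grid coarser than shortest frame")

    def average(self, node_values: np.ndarray, delay_s: float = 0.0) -> np.ndarray:
        """Frame means of the delayed curve f(t - delay_s)."""
        samp = np.interp(self.mid_t - delay_s, self.node_t, node_values, left=0.0)
        sums = np.add.reduceat(samp, self.edges[:-1])
        return sums / self.counts


def convolve_residue_input(
    residue_vals: np.ndarray, input_vals: np.ndarray, fine_dt_s: float
) -> np.ndarray:
    """Discrete convolution of a residue with an input curve on a shared grid.

    Both arrays are tabulated on the same uniform grid; the result
    approximates integral_0^t R(t - s) Cp(s) ds with the time step
    converted to minutes (residues are per-minute quantities).
    """
    n = residue_vals.size
    full = np.convolve(residue_vals, input_vals)[:n]
    return full * (fine_dt_s / SEC_PER_MIN)
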