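"""Tissue residue functions, their decomposition, and kinetic parameters.

A residue is a nonnegative nonincreasing piecewise-linear function of time
(seconds) in flow units (mL/min/g).  Splitting it at a vascular transit
threshold t* and at the end of acquisition yields three components:

* a vascular component (transit faster than t*),
* an in-distribution component (exchanging but not retained), and
* an extracted component (the constant floor, retained tracer),

from which volumes, flows, mean transit time and the extraction fraction
are read off as areas and amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import SEC_PER_MIN

__all__ = [
    "Residue",
    "ResidueDecomposition",
    "KineticParams",
    "DerivedVars",
    "decompose",
    "kinetic_params",
    "derived_vars",
    "DEFAULT_T_STAR_S",
]

DEFAULT_T_STAR_S = 15.0
ADMISSIBILITY_RTOL = 1e-8
KD_EPS = 1e-9


@dataclass(frozen=True)
class Residue:
    """Nonincreasing, nonnegative piecewise-linear residue on a time grid.

    Violations of admissibility larger than a 1e-8 relative tolerance
    raise; smaller ones (numerical noise) are clipped at construction.
    """

    grid_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid_s, dtype=float)
        v = np.asarray(self.values, dtype=float).copy()
        if g.ndim != 1 or g.shape != v.shape or g.size < 2:
            raise ValueError("grid and values must be 1-d arrays of equal length >= 2")
        if g[0] != 0.0:
            raise ValueError("residue grid must start at 0")
        if np.any(np.diff(g) <= 0):
            raise ValueError("residue grid must be strictly increasing")
        if np.any(~np.isfinite(v)):
            raise ValueError("residue values must be finite")
        scale = max(float(np.max(np.abs(v))), 1.0e-300)
        tol = ADMISSIBILITY_RTOL * scale
        if np.any(v < -tol):
            raise ValueError("residue values must be nonnegative")
        if np.any(np.diff(v) > tol):
            raise ValueError("residue values must be nonincreasing")
        # clip sub-tolerance violations exactly
        v = np.minimum.accumulate(np.clip(v, 0.0, None))
        object.__setattr__(self, "grid_s", g)
        object.__setattr__(self, "values", v)

    @property
    def T_end_s(self) -> float:
        return float(self.grid_s[-1])

    def __call__(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.grid_s, self.values)

    def with_knots(self, extra_s) -> "Residue":
        """Refine the grid to include the given knots (values interpolated)."""
        g = np.union1d(self.grid_s, np.asarray(extra_s, dtype=float))
        g = g[(g >= 0.0) & (g <= self.T_end_s)]
        return Residue(g, self(g))

    def restricted(self, T_end_s: float) -> "Residue":
        """Restrict to [0, T_end_s] (a knot is inserted at the endpoint)."""
        if T_end_s > self.T_end_s + 1e-9:
            raise ValueError("residue not defined through requested end time")
        g = np.union1d(self.grid_s[self.grid_s < T_end_s], [T_end_s])
        return Residue(g, self(g))

    def scaled(self, c: float) -> "Residue":
        if c < 0:
            raise ValueError("scale factor must be nonnegative")
        return Residue(self.grid_s, c * self.values)

    def integral_min(self) -> float:
        """Area under the residue over its grid, time in minutes."""
        return float(np.trapezoid(self.values, self.grid_s)) / SEC_PER_MIN


@dataclass(frozen=True)
class ResidueDecomposition:
    """Vascular / in-distribution / extracted split of a residue."""

    R_b: Residue
    R_d: Residue
    R_e: Residue
    t_star_s: float
    T_end_s: float

    @property
    def total(self) -> Residue:
        return Residue(self.R_b.grid_s, self.R_b.values + self.R_d.values + self.R_e.values)


@dataclass(frozen=True)
class KineticParams:
    """Six residue-derived kinetic parameters for one voxel or region.

    MTT_min is NaN when the distribution flow K_d is numerically zero;
    Ext is NaN when both K_d and K_i vanish.
    """

    V_b: float  # mL/g
    V_d: float  # mL/g
    K_d: float  # mL/min/g
    K_i: float  # mL/min/g
    MTT_min: float
    Ext: float  # fraction in [0, 1]
    delay_s: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "V_b": self.V_b,
            "V_d": self.V_d,
            "K_d": self.K_d,
            "K_i": self.K_i,
            "MTT": self.MTT_min,
            "Ext": self.Ext,
            "delay_s": self.delay_s,
        }


@dataclass(frozen=True)
class DerivedVars:
    MR_FDG: float  # umol/100 g/min
    DV: float  # mL/g
    BF: float  # mL/min/g
    mu_glc: float  # mmol/L


def decompose(
    residue: Residue,
    t_star_s: float = DEFAULT_T_STAR_S,
    T_end_s: float | None = None,
) -> ResidueDecomposition:
    """Split a residue at the vascular threshold and the acquisition end.

    R_b(t) = [R(t) - R(t*)] for t < t*, else 0; R_e is the constant
    R(T_end); R_d is the remainder (held at its t* value below t*).
    The components sum to R pointwise on the refined grid.
    """
    if T_end_s is None:
        T_end_s = residue.T_end_s
    if not (0.0 < t_star_s < T_end_s):
        raise ValueError("need 0 < t_star_s < T_end_s")
    if T_end_s > residue.T_end_s + 1e-9:
        raise ValueError("residue not defined at T_end_s")
    base = residue.restricted(T_end_s).with_knots([t_star_s])
    g = base.grid_s
    r = base.values
    r_star = float(base(t_star_s))
    r_end = float(r[-1])
    vb = np.where(g < t_star_s, np.clip(r - r_star, 0.0, None), 0.0)
    ve = np.full_like(r, r_end)
    vd = np.clip(r - vb - ve, 0.0, None)
    return ResidueDecomposition(
        R_b=Residue(g, vb),
        R_d=Residue(g, vd),
        R_e=Residue(g, ve),
        t_star_s=float(t_star_s),
        T_end_s=float(T_end_s),
    )


def kinetic_params(
    dec: ResidueDecomposition,
    ext_convention: str = "retained",
    delay_s: float = 0.0,
) -> KineticParams:
    """Volumes, flows, transit time and extraction from a decomposition.

    V_b and V_d are the areas under R_b and R_d (minutes); K_i is the
    residue height at the end of acquisition; K_d the in-distribution
    height at time 0; MTT = V_d / K_d.  ``ext_convention`` selects
    K_i/(K_d + K_i) (default, a retained fraction in [0, 1]) or the
    ratio-to-distribution-flow alternative K_i/K_d.
    """
    V_b = dec.R_b.integral_min()
    V_d = dec.R_d.integral_min()
    K_i = float(dec.R_e.values[0])
    K_d = float(dec.R_d(0.0))
    MTT = V_d / K_d if K_d > KD_EPS else float("nan")
    if ext_convention == "retained":
        denom = K_d + K_i
        Ext = K_i / denom if denom > KD_EPS else float("nan")
    elif ext_convention == "ratio":
        Ext = K_i / K_d if K_d > KD_EPS else float("nan")
    else:
        raise ValueError(f"unknown ext_convention: {ext_convention!r}")
    return KineticParams(
        V_b=V_b, V_d=V_d, K_d=K_d, K_i=K_i, MTT_min=MTT, Ext=Ext, delay_s=delay_s
    )


def derived_vars(
    params: KineticParams, mu_glc_mmol_l: float, t_star_s: float = DEFAULT_T_STAR_S
) -> DerivedVars:
    """Metabolic rate, distribution volume and blood flow.

    MR_FDG = mu_glc * K_i converted to umol/100 g/min (mmol/L equals
    umol/mL, and the per-gram flux is scaled to 100 g); BF applies the
    central-volume theorem with a vascular mean transit time of t*/2.
    """
    if mu_glc_mmol_l <= 0:
        raise ValueError("plasma glucose must be positive")
    mr = mu_glc_mmol_l * params.K_i * 100.0
    bf = params.V_b / ((t_star_s / 2.0) / SEC_PER_MIN)
    return DerivedVars(MR_FDG=mr, DV=params.V_d, BF=bf, mu_glc=mu_glc_mmol_l)
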