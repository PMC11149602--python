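"""Voxel- and region-level nonnegative least-squares fitting on a tissue basis.

Each time course z(t_j) is modeled as sum_k alpha_k mu_k(t_j - delta) with
alpha >= 0; amplitudes are found by NNLS (a nonnegative quadratic program)
for each candidate delay on a crude grid, and the best-misfit delay wins.
Kinetic maps follow by assembling the voxel residue sum_k alpha_k R_k:
V_b, V_d, K_d and K_i are linear in alpha, so maps are a matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import TissueBasisSet, _weighted_nnls
from .frames import FitWeights
from .image import DynamicImage, KineticMaps, embed
from .residue import DEFAULT_T_STAR_S, KD_EPS, Residue

__all__ = [
    "VoxelFit",
    "FlatFits",
    "fit_voxel",
    "fit_tacs",
    "fit_image",
    "fit_voi_tac",
    "params_from_alpha",
    "default_voxel_delay_grid",
    "voi_delay_grid",
]


def default_voxel_delay_grid() -> np.ndarray:
    return np.arange(-10.0, 30.0 + 1e-9, 2.0)


def voi_delay_grid(half_range_s: float = 300.0, step_s: float = 2.0) -> np.ndarray:
    return np.arange(-half_range_s, half_range_s + 1e-9, step_s)


@dataclass
class VoxelFit:
    """One fitted time course: amplitudes, delay, fit, and misfit."""

    alpha: np.ndarray
    delay_s: float
    fitted: np.ndarray
    wrss: float
    ok: bool = True

    def residue(self, basis: TissueBasisSet) -> Residue:
        """Implied residue sum_k alpha_k R_k on a common grid."""
        grid = basis.residues[0].grid_s
        for r in basis.residues[1:]:
            grid = np.union1d(grid, r.grid_s)
        vals = np.zeros(grid.size)
        for a, r in zip(self.alpha, basis.residues):
            vals += a * r(grid)
        return Residue(grid, vals)


@dataclass
class FlatFits:
    """Vectorized per-voxel fit results over the masked voxels."""

    alpha: np.ndarray  # (N, K)
    delay_s: np.ndarray  # (N,)
    wrss: np.ndarray  # (N,)
    fitted: np.ndarray  # (N, J)
    ok: np.ndarray  # (N,) bool; False = skipped / degenerate

    @property
    def n(self) -> int:
        return self.alpha.shape[0]


def fit_voxel(
    tac: np.ndarray,
    basis: TissueBasisSet,
    weights: FitWeights,
    delta_grid_s: np.ndarray | None = None,
) -> VoxelFit:
    """Weighted NNLS over the basis with a grid search on the voxel delay."""
    tac = np.asarray(tac, dtype=float)
    if delta_grid_s is None:
        delta_grid_s = default_voxel_delay_grid()
    delta_grid_s = np.atleast_1d(np.asarray(delta_grid_s, dtype=float))
    mats = [basis.frame_matrix(d) for d in delta_grid_s]
    if all(not np.any(M) for M in mats):
        J = tac.size
        return VoxelFit(np.zeros(basis.K), 0.0, np.zeros(J), float(np.sum(weights.w * tac**2)), ok=False)
    best = None
    for d, M in zip(delta_grid_s, mats):
        alpha, wrss = _weighted_nnls(M, tac, weights.w)
        if best is None or wrss < best[2]:
            best = (alpha, float(d), wrss, M)
    alpha, delay, wrss, M = best
    return VoxelFit(alpha, delay, M @ alpha, wrss)


def fit_tacs(
    tacs: np.ndarray,
    basis: TissueBasisSet,
    weights: FitWeights,
    delta_grid_s: np.ndarray | None = None,
    signal_floor_frac: float = 1e-3,
) -> FlatFits:
    """Fit many time courses; low-signal voxels are skipped and flagged."""
    tacs = np.asarray(tacs, dtype=float)
    N, J = tacs.shape
    if delta_grid_s is None:
        delta_grid_s = default_voxel_delay_grid()
    delta_grid_s = np.atleast_1d(np.asarray(delta_grid_s, dtype=float))
    mats = [basis.frame_matrix(d) for d in delta_grid_s]
    w = weights.w
    sw = np.sqrt(w)
    scaled = [(M * sw[:, None], d) for M, d in zip(mats, delta_grid_s)]

    signal = np.abs(tacs) @ w
    floor = signal_floor_frac * (signal.max() if signal.size else 0.0)

    from scipy.optimize import nnls

    alpha = np.zeros((N, basis.K))
    delay = np.zeros(N)
    wrss = np.zeros(N)
    fitted = np.zeros((N, J))
    ok = np.ones(N, dtype=bool)
    for i in range(N):
        if signal[i] <= floor:
            ok[i] = False
            wrss[i] = float(np.sum(w * tacs[i] ** 2))
            continue
        zi = tacs[i] * sw
        best = None
        for (Msw, d), M in zip(scaled, mats):
            a, rnorm = nnls(Msw, zi)
            r2 = rnorm**2
            if best is None or r2 < best[1]:
                best = (a, r2, float(d), M)
        a, r2, d, M = best
        alpha[i] = a
        wrss[i] = r2
        delay[i] = d
        fitted[i] = M @ a
    return FlatFits(alpha, delay, wrss, fitted, ok)


def params_from_alpha(
    fits: FlatFits,
    basis: TissueBasisSet,
    t_star_s: float = DEFAULT_T_STAR_S,
    ext_convention: str = "retained",
) -> dict[str, np.ndarray]:
    """Per-voxel kinetic parameters from fitted amplitudes.

    Uses the linearity of V_b, V_d, K_d and K_i in the residue; MTT and
    Ext follow as ratios.  Skipped voxels come back NaN.
    """
    P = basis.residue_param_table(t_star_s, ext_convention)  # (K, 4)
    lin = fits.alpha @ P
    V_b, V_d, K_d, K_i = lin.T.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        MTT = np.where(K_d > KD_EPS, V_d / K_d, np.nan)
        if ext_convention == "retained":
            denom = K_d + K_i
            Ext = np.where(denom > KD_EPS, K_i / denom, np.nan)
        else:
            Ext = np.where(K_d > KD_EPS, K_i / K_d, np.nan)
    out = {
        "V_b": V_b,
        "V_d": V_d,
        "K_d": K_d,
        "K_i": K_i,
        "MTT": MTT,
        "Ext": Ext,
        "delay_s": fits.delay_s.astype(float).copy(),
        "wrss": fits.wrss.copy(),
    }
    bad = ~fits.ok
    for key in ("V_b", "V_d", "K_d", "K_i", "MTT", "Ext", "delay_s"):
        out[key][bad] = np.nan
    return out


def fit_image(
    image: DynamicImage,
    basis: TissueBasisSet,
    weights: FitWeights,
    delta_grid_s: np.ndarray | None = None,
    t_star_s: float = DEFAULT_T_STAR_S,
    ext_convention: str = "retained",
    signal_floor_frac: float = 1e-3,
) -> tuple[KineticMaps, FlatFits]:
    """Voxelwise fit of a dynamic image; masked-out voxels are NaN."""
    if image.schedule.J != basis.schedule.J or not np.allclose(
        image.schedule.start_s, basis.schedule.start_s
    ):
        raise ValueError("image frame schedule does not match the basis schedule")
    tacs = image.masked_tacs()
    fits = fit_tacs(tacs, basis, weights, delta_grid_s, signal_floor_frac)
    flat = params_from_alpha(fits, basis, t_star_s, ext_convention)
    maps = {k: embed(image.body_mask, v) for k, v in flat.items()}
    return KineticMaps(maps, image.body_mask, image.voxel_size_mm), fits


def fit_voi_tac(
    mean_tac: np.ndarray,
    basis: TissueBasisSet,
    weights: FitWeights,
    delta_half_range_s: float = 300.0,
    delta_step_s: float = 2.0,
) -> VoxelFit:
    """Fit a region-mean curve; a wide +/- delay range is allowed."""
    return fit_voxel(
        mean_tac, basis, weights, voi_delay_grid(delta_half_range_s, delta_step_s)
    )
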