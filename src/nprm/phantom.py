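"""Synthetic 4-D dynamic phantoms with known ground truth.

Organs are ellipsoids on a small voxel grid, each carrying a known
admissible residue (compartmental or not) and input delay.  Noiseless
frame signals come from the residue-input convolution; noise follows the
factored scale model sigma_e * psi_i * phi_j * eps with eps drawn from a
standardized skewed (shifted-gamma) family, optionally spatially smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import _ConvolutionEngine
from .comp2c import TwoCParams, residue_2c
from .frames import FrameSchedule, InputFunction, build_schedule
from .image import DynamicImage, KineticMaps, embed
from .residue import DEFAULT_T_STAR_S, Residue, decompose, kinetic_params

__all__ = [
    "AifParams",
    "NoiseSpec",
    "Organ",
    "PhantomSpec",
    "make_aif",
    "simulate_image",
    "simulate_mixture_image",
    "standard_phantoms",
    "default_phantom_schedule",
]


@dataclass(frozen=True)
class AifParams:
    """Bolus input: gamma-variate peak plus a two-exponential washout tail.

    With tail amplitudes zero the curve is a pure gamma-variate whose peak
    sits at ``injection_s + shape * scale_s``.
    """

    dose: float = 50.0  # peak-scale amplitude, kBq/mL
    injection_s: float = 15.0
    shape: float = 3.0
    scale_s: float = 8.0
    tail_amps: tuple[float, float] = (0.12, 0.05)
    tail_rates_per_min: tuple[float, float] = (0.15, 0.01)
    tail_rise_s: float = 30.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale_s <= 0 or self.dose <= 0:
            raise ValueError("gamma-variate shape, scale and dose must be positive")
        if any(a < 0 for a in self.tail_amps):
            raise ValueError("tail amplitudes must be nonnegative")

    def curve(self, t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, dtype=float) - self.injection_s
        out = np.zeros_like(t)
        pos = t > 0
        u = t[pos] / self.scale_s
        g = (u**self.shape) * np.exp(-u)
        g = g / (self.shape**self.shape * np.exp(-self.shape))  # unit peak at t = shape*scale
        tail = np.zeros_like(u)
        ramp = 1.0 - np.exp(-t[pos] / self.tail_rise_s)
        for amp, rate in zip(self.tail_amps, self.tail_rates_per_min):
            tail += amp * ramp * np.exp(-rate * t[pos] / 60.0)
        out[pos] = self.dose * (g + tail)
        return out


def make_aif(
    params: AifParams, schedule: FrameSchedule, fine_dt_s: float = 1.0
) -> InputFunction:
    """Sampled input curve covering the schedule on a fine grid."""
    t = np.arange(0.0, schedule.total_duration_s + fine_dt_s, fine_dt_s)
    return InputFunction(t, params.curve(t))


@dataclass(frozen=True)
class Organ:
    name: str
    center: tuple[float, float, float]  # fractional grid coordinates in [0, 1]
    radii: tuple[float, float, float]  # fractional semi-axes
    residue: Residue | TwoCParams
    delay_s: float = 0.0

    def mask(self, dims: tuple[int, int, int]) -> np.ndarray:
        grids = np.meshgrid(
            *[np.arange(d) / max(d - 1, 1) for d in dims], indexing="ij"
        )
        acc = np.zeros(dims)
        for g, c, r in zip(grids, self.center, self.radii):
            acc += ((g - c) / r) ** 2
        return acc <= 1.0


@dataclass(frozen=True)
class NoiseSpec:
    sigma_e: float = 0.0
    skewness: float = 1.5
    psi_axial_amplitude: float = 0.0  # U-shaped axial scale pattern strength
    smooth_fwhm_voxels: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_e < 0:
            raise ValueError("noise scale must be nonnegative")


@dataclass(frozen=True)
class PhantomSpec:
    dims: tuple[int, int, int] = (32, 32, 48)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    organs: tuple[Organ, ...] = ()
    aif: AifParams = field(default_factory=AifParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0


def _organ_residue(organ: Organ, t_star_s: float, T_end_s: float) -> Residue:
    if isinstance(organ.residue, TwoCParams):
        return residue_2c(organ.residue, t_star_s, T_end_s)
    return organ.residue


def _skewed_unit_noise(rng: np.random.Generator, size, skewness: float) -> np.ndarray:
    """Mean-0, variance-1 draws with the requested (right) skewness."""
    if skewness <= 0:
        return rng.standard_normal(size)
    k = 4.0 / skewness**2
    return (rng.gamma(k, 1.0, size) - k) / np.sqrt(k)


def _u_shaped_psi(dims: tuple[int, int, int], amplitude: float) -> np.ndarray:
    z = np.arange(dims[2]) / max(dims[2] - 1, 1)
    prof = 1.0 + amplitude * (2.0 * z - 1.0) ** 2
    psi = np.broadcast_to(prof[None, None, :], dims).copy()
    return psi / np.sqrt(np.mean(psi**2))


def simulate_image(
    spec: PhantomSpec,
    schedule: FrameSchedule,
    t_star_s: float = DEFAULT_T_STAR_S,
    fine_dt_s: float = 1.0,
) -> tuple[DynamicImage, KineticMaps, np.ndarray, InputFunction]:
    """Forward-simulate a phantom.

    Returns (dynamic image, ground-truth kinetic maps, organ label volume,
    input function).  Reproducible from ``spec.seed``.
    """
    aif = make_aif(spec.aif, schedule, fine_dt_s)
    engine = _ConvolutionEngine(schedule, aif, fine_dt_s)
    node_t = engine.binner.node_t
    T_end = schedule.total_duration_s

    labels = np.zeros(spec.dims, dtype=int)
    clean = np.zeros(spec.dims + (schedule.J,))
    organ_params = []
    for i, organ in enumerate(spec.organs, start=1):
        residue = _organ_residue(organ, t_star_s, T_end)
        if residue.T_end_s < T_end - 1e-9:
            raise ValueError(f"organ {organ.name!r} residue not defined through T_end")
        curve = engine.frame_average(engine.convolve(residue(node_t), organ.delay_s))[:, 0]
        m = organ.mask(spec.dims)
        labels[m] = i
        clean[m] = curve
        organ_params.append(kinetic_params(decompose(residue, t_star_s, T_end), delay_s=organ.delay_s))
    mask = labels > 0

    names = ("V_b", "V_d", "K_d", "K_i", "MTT", "Ext", "delay_s")
    truth_maps = {}
    for name in names:
        vol = np.full(spec.dims, np.nan)
        for i, p in enumerate(organ_params, start=1):
            vol[labels == i] = p.as_dict()[name]
        truth_maps[name] = vol

    rng = np.random.default_rng(spec.seed)
    data = clean.copy()
    if spec.noise.sigma_e > 0:
        eps = _skewed_unit_noise(rng, spec.dims + (schedule.J,), spec.noise.skewness)
        if spec.noise.smooth_fwhm_voxels > 0:
            from scipy.ndimage import gaussian_filter

            sd = spec.noise.smooth_fwhm_voxels / 2.3548
            eps = gaussian_filter(eps, sigma=(sd, sd, sd, 0.0), mode="nearest")
            eps /= eps.std()
        psi = _u_shaped_psi(spec.dims, spec.noise.psi_axial_amplitude)
        w = np.ones(schedule.J) / schedule.J
        phi = 1.0 / np.sqrt(schedule.duration_s / schedule.duration_s.max())
        phi = phi / np.sqrt(np.sum(w * phi**2))
        data = clean + spec.noise.sigma_e * psi[..., None] * phi[None, None, None, :] * eps

    image = DynamicImage(
        data=data,
        voxel_size_mm=spec.voxel_size_mm,
        schedule=schedule,
        body_mask=mask,
    )
    truth = KineticMaps(truth_maps, mask, spec.voxel_size_mm)
    return image, truth, labels, aif


def simulate_mixture_image(
    residues: list[Residue],
    delays_s,
    schedule: FrameSchedule,
    dims: tuple[int, int, int],
    noise: NoiseSpec,
    seed: int = 0,
    aif_params: AifParams | None = None,
    amp_range: tuple[float, float] = (0.4, 1.2),
    fine_dt_s: float = 1.0,
):
    """Phantom whose voxels are smooth positive mixtures of all residues.

    Amplitude fields vary linearly along different axes within
    ``amp_range``, keeping every voxel's amplitudes well inside the
    positive orthant (no active-set boundary effects).  Returns
    ``(tacs (N, J), truth_alpha (N, K), aif)`` in flattened voxel order.
    """
    aif = make_aif(aif_params or AifParams(), schedule, fine_dt_s)
    engine = _ConvolutionEngine(schedule, aif, fine_dt_s)
    node_t = engine.binner.node_t
    curves = np.column_stack(
        [
            engine.frame_average(engine.convolve(r(node_t), d))[:, 0]
            for r, d in zip(residues, delays_s)
        ]
    )
    N = int(np.prod(dims))
    K = len(residues)
    grids = np.meshgrid(*[np.linspace(0.0, 1.0, d) for d in dims], indexing="ij")
    lo, hi = amp_range
    fields = []
    for k in range(K):
        g = grids[k % 3] if k % 2 == 0 else 1.0 - grids[k % 3]
        fields.append(lo + (hi - lo) * g)
    alpha = np.stack(fields, axis=-1).reshape(N, K)
    clean = alpha @ curves.T
    rng = np.random.default_rng(seed)
    data = clean
    if noise.sigma_e > 0:
        eps = _skewed_unit_noise(rng, (N, schedule.J), noise.skewness)
        psi = _u_shaped_psi(dims, noise.psi_axial_amplitude).reshape(N)
        w = np.ones(schedule.J) / schedule.J
        phi = 1.0 / np.sqrt(schedule.duration_s / schedule.duration_s.max())
        phi = phi / np.sqrt(np.sum(w * phi**2))
        data = clean + noise.sigma_e * psi[:, None] * phi[None, :] * eps
    return data, alpha, aif


def default_phantom_schedule() -> FrameSchedule:
    """The 62-frame, 65-minute acquisition layout used throughout."""
    return build_schedule([(2, 10), (30, 2), (4, 10), (8, 30), (4, 60), (5, 120), (9, 300)])


def _flat_residue(level: float, T_end_s: float) -> Residue:
    return Residue(np.array([0.0, T_end_s]), np.array([level, level]))


def _plateau_residue(
    k0: float, plateau_s: float, ki: float, tau_min: float, T_end_s: float
) -> Residue:
    """Non-exponential residue: flat at k0 until plateau_s, then exponential
    approach to the retention floor ki -- a shape no 2-exponential fits."""
    grid = np.union1d(
        np.union1d(np.arange(0.0, 61.0, 2.0), np.arange(60.0, T_end_s + 1e-9, 10.0)),
        [plateau_s, T_end_s],
    )
    vals = np.where(
        grid <= plateau_s,
        k0,
        ki + (k0 - ki) * np.exp(-(grid - plateau_s) / (60.0 * tau_min)),
    )
    return Residue(grid, vals)


def standard_phantoms(
    dims: tuple[int, int, int] = (16, 16, 24),
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> dict[str, PhantomSpec]:
    """Named desk-scale phantom presets.

    * ``twocomp`` -- all organs follow the 2-compartment model;
    * ``mixed``   -- organs with plateau-type residues a compartmental
      (sum of exponentials) residue cannot represent;
    * ``flat``    -- constant residues (pure-trapping limit).
    """
    if noise is None:
        noise = NoiseSpec()
    T_end = default_phantom_schedule().total_duration_s
    geometry = [
        ("organ_a", (0.30, 0.30, 0.30), (0.28, 0.28, 0.22)),
        ("organ_b", (0.70, 0.65, 0.45), (0.26, 0.30, 0.22)),
        ("organ_c", (0.40, 0.70, 0.75), (0.30, 0.26, 0.20)),
    ]

    twoc = [
        TwoCParams(0.30, 0.40, 0.06, 0.0, 0.05),  # gray-matter-like
        TwoCParams(0.55, 0.65, 0.01, 0.0, 0.09),  # liver-like
        TwoCParams(0.10, 0.60, 0.03, 0.0, 0.16),  # lung-like
    ]
    mixed = [
        _plateau_residue(0.55, 45.0, 0.04, 1.2, T_end),  # liver-like washout shelf
        _plateau_residue(0.45, 90.0, 0.01, 2.5, T_end),  # kidney-like
        residue_2c(TwoCParams(0.30, 0.40, 0.06, 0.0, 0.05), T_end_s=T_end),
    ]
    flat = [_flat_residue(c, T_end) for c in (0.02, 0.05, 0.10)]

    def build(residues, delays=(0.0, 4.0, 8.0)):
        organs = tuple(
            Organ(name, center, radii, res, delay)
            for (name, center, radii), res, delay in zip(geometry, residues, delays)
        )
        return PhantomSpec(dims=dims, organs=organs, noise=noise, seed=seed)

    return {
        "twocomp": build(twoc),
        "mixed": build(mixed),
        "flat": build(flat, delays=(0.0, 0.0, 0.0)),
    }
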