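"""4-D dynamic image container and parameter-map container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import FrameSchedule

__all__ = ["DynamicImage", "KineticMaps", "embed"]


@dataclass
class DynamicImage:
    """Voxel-by-frame decay-corrected activity with geometry and mask."""

    data: np.ndarray  # (X, Y, Z, J), kBq/mL
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule
    body_mask: np.ndarray | None = None  # (X, Y, Z) bool
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic image data must be 4-d (x, y, z, frame)")
        if self.data.shape[-1] != self.schedule.J:
            raise ValueError(
                f"image has {self.data.shape[-1]} frames but schedule has "
                f"{self.schedule.J}"
            )
        if np.any(~np.isfinite(self.data)):
            raise ValueError("dynamic image contains non-finite voxels")
        if self.body_mask is None:
            self.body_mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.body_mask = np.asarray(self.body_mask, dtype=bool)
            if self.body_mask.shape != self.data.shape[:3]:
                raise ValueError("body mask shape must match the image grid")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_masked(self) -> int:
        return int(self.body_mask.sum())

    def masked_tacs(self) -> np.ndarray:
        """Time-activity curves of in-mask voxels, shape (N, J)."""
        return self.data[self.body_mask]

    def mask_indices(self) -> np.ndarray:
        """(N, 3) voxel indices of in-mask voxels, same order as masked_tacs."""
        return np.argwhere(self.body_mask)


def embed(mask: np.ndarray, flat: np.ndarray, fill: float = np.nan) -> np.ndarray:
    """Scatter per-masked-voxel values back into a 3-d volume."""
    out = np.full(mask.shape, fill, dtype=float)
    out[mask] = flat
    return out


@dataclass
class KineticMaps:
    """Per-parameter 3-d maps; out-of-mask voxels are NaN, not zero."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    units: dict[str, str] = field(default_factory=dict)

    PARAM_UNITS = {
        "V_b": "mL/g",
        "V_d": "mL/g",
        "K_d": "mL/min/g",
        "K_i": "mL/min/g",
        "MTT": "min",
        "Ext": "fraction",
        "delay_s": "s",
        "wrss": "weighted-sum-of-squares",
    }

    def __post_init__(self) -> None:
        if not self.units:
            self.units = {k: self.PARAM_UNITS.get(k, "") for k in self.maps}

    def __getitem__(self, key: str) -> np.ndarray:
        return self.maps[key]

    def keys(self):
        return self.maps.keys()
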