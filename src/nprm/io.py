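"""Readers and writers for on-disk artifacts (NIfTI, CSV, JSON manifests)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .frames import FrameSchedule, InputFunction
from .image import DynamicImage, KineticMaps

__all__ = [
    "read_dynamic",
    "write_dynamic",
    "read_mask",
    "write_labels",
    "read_schedule_csv",
    "write_schedule_csv",
    "read_aif_csv",
    "write_aif_csv",
    "write_maps",
    "write_manifest",
    "read_manifest",
]


def read_schedule_csv(path, isotope_halflife_min: float | None = None) -> FrameSchedule:
    df = pd.read_csv(path)
    kwargs = {}
    if isotope_halflife_min is not None:
        kwargs["isotope_halflife_min"] = isotope_halflife_min
    return FrameSchedule(
        df["start_s"].to_numpy(float), df["duration_s"].to_numpy(float), **kwargs
    )


def write_schedule_csv(schedule: FrameSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_aif_csv(path) -> InputFunction:
    df = pd.read_csv(path)
    return InputFunction(
        df["time_s"].to_numpy(float), df["activity_kBq_ml"].to_numpy(float)
    )


def write_aif_csv(aif: InputFunction, path) -> None:
    aif.to_frame().to_csv(path, index=False)


def read_dynamic(
    path, schedule: FrameSchedule, mask_path=None
) -> DynamicImage:
    """Load a 4-D NIfTI; the frame count must match the schedule."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-d image, got shape {data.shape}")
    if data.shape[-1] != schedule.J:
        raise ValueError(
            f"image has {data.shape[-1]} frames but the schedule has {schedule.J}"
        )
    n_bad = int(np.sum(~np.isfinite(data)))
    if n_bad:
        raise ValueError(f"image contains {n_bad} non-finite voxels")
    zooms = img.header.get_zooms()[:3]
    mask = None
    if mask_path is not None:
        mask = read_mask(mask_path) > 0
    return DynamicImage(
        data=data,
        voxel_size_mm=tuple(float(z) for z in zooms),
        schedule=schedule,
        body_mask=mask,
        affine=img.affine,
    )


def write_dynamic(image: DynamicImage, path) -> None:
    nib.save(nib.Nifti1Image(image.data, image.affine), str(path))


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_labels(labels: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(path))


def write_maps(
    maps: KineticMaps,
    out_dir,
    affine: np.ndarray | None = None,
    conventions: dict | None = None,
    prefix: str = "",
) -> None:
    """One 3-D NIfTI per parameter plus a JSON sidecar recording units."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.diag(list(maps.voxel_size_mm) + [1.0])
    for name in maps.keys():
        nib.save(
            nib.Nifti1Image(maps[name].astype(np.float64), affine),
            str(out / f"{prefix}{name}.nii.gz"),
        )
    sidecar = {"units": maps.units, "conventions": conventions or {}}
    (out / f"{prefix}maps.json").write_text(json.dumps(sidecar, indent=2))


def write_manifest(out_dir, payload: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(payload, indent=2, default=str))


def read_manifest(out_dir) -> dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())
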