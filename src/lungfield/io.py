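"""Reading CT inputs and writing masks/reports.

Supported input formats: a DICOM series directory (rescale slope/intercept
applied, slices ordered by ImagePositionPatient z), a NIfTI volume (axis 2 =
slice), or PNG/TIFF images with an explicit HU rescale ``(slope, intercept)``.
Masks are written as 0/255 PNGs per slice and optionally as a NIfTI volume
mirroring the source geometry.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

__all__ = [
    "read_ct",
    "read_dicom_dir",
    "read_nifti",
    "read_image_with_rescale",
    "write_mask_png",
    "write_mask_nifti",
    "write_stack_nifti",
]


def read_dicom_dir(path) -> np.ndarray:
    """Read a single-series DICOM directory into an HU stack (S, H, W)."""
    import pydicom

    files = sorted(
        p for p in Path(path).iterdir()
        if p.is_file() and not p.name.startswith(".")
    )
    if not files:
        raise FileNotFoundError(f"no files in DICOM directory {path}")
    datasets = [pydicom.dcmread(str(p)) for p in files]
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"directory {path} mixes {len(uids)} DICOM series")

    def _z(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=_z)
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    return np.stack(slices)


def read_nifti(path) -> np.ndarray:
    """Read a NIfTI volume; axis 2 of the file is the slice axis."""
    import nibabel as nib

    vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    if vol.ndim == 2:
        return vol[None, ...]
    return np.moveaxis(vol, 2, 0)


def read_image_with_rescale(path, slope: float, intercept: float) -> np.ndarray:
    """Read a PNG/TIFF slice and map stored values to HU linearly."""
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(str(path)), dtype=np.float64)
    if raw.ndim == 3:
        raw = raw[..., 0]
    return raw[None, ...] * slope + intercept


def read_ct(path, fmt: str | None = None, slope: float | None = None,
            intercept: float | None = None) -> np.ndarray:
    """Read a CT input into an HU-valued stack of shape (S, H, W).

    ``fmt`` is one of ``{"dicom-dir", "nifti", "png-with-rescale"}``; when
    omitted it is inferred from the path (directory -> DICOM series,
    ``.nii``/``.nii.gz`` -> NIfTI, else image-with-rescale).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if fmt is None:
        if p.is_dir():
            fmt = "dicom-dir"
        elif p.name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        else:
            fmt = "png-with-rescale"
    if fmt == "dicom-dir":
        return read_dicom_dir(p)
    if fmt == "nifti":
        return read_nifti(p)
    if fmt == "png-with-rescale":
        if slope is None or intercept is None:
            raise ValueError(
                "PNG/TIFF input needs an explicit HU rescale (slope, intercept)"
            )
        return read_image_with_rescale(p, slope, intercept)
    raise ValueError(f"unknown format {fmt!r}")


def write_mask_png(mask: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_mask_nifti(stack, path, affine=None) -> None:
    """Write a boolean slice stack as a uint8 NIfTI (slice axis back to axis 2)."""
    import nibabel as nib

    arr = np.moveaxis(np.asarray(stack, dtype=np.uint8), 0, 2)
    nib.save(nib.Nifti1Image(arr, np.eye(4) if affine is None else affine), str(path))


def write_stack_nifti(stack, path, affine=None) -> None:
    import nibabel as nib

    arr = np.moveaxis(np.asarray(stack, dtype=np.float64), 0, 2)
    nib.save(nib.Nifti1Image(arr, np.eye(4) if affine is None else affine), str(path))
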