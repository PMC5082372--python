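"""Grayscale slice readers and writers (PNG, TIFF, DICOM, NIfTI).

Intensities pass through untouched — no window/level is applied on read, so
what the pipeline sees is what the file stores (after the DICOM rescale
slope/intercept, which maps stored values to the modality scale).  3D
volumes (NIfTI, multi-frame DICOM) need an explicit slice index: the
pipeline is strictly 2D.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .image import GrayImage, round_half_up

__all__ = ["read_gray", "write_gray"]

_RASTER_EXTS = {".png", ".tif", ".tiff"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = path.suffix.lower()
    if ext in (".png",):
        return "png"
    if ext in (".tif", ".tiff"):
        return "tiff"
    if ext in (".dcm", ".dicom"):
        return "dicom"
    if ext in (".nii",) or path.name.lower().endswith(".nii.gz"):
        return "nifti"
    raise ValueError(f"cannot infer image format from {path.name!r}; pass format=")


def _levels_for(arr: np.ndarray, levels: int | None) -> int:
    if levels is not None:
        return levels
    return 65536 if arr.max() > 255 else 256


def read_gray(
    path: str | os.PathLike,
    format: str | None = None,
    levels: int | None = None,
    slice_index: int | None = None,
    rgb: str = "error",
) -> GrayImage:
    """Read a single 2D grayscale slice.

    Parameters
    ----------
    format : {"png", "tiff", "dicom", "nifti"}, optional
        Inferred from the extension when omitted.
    levels : int, optional
        Declared gray-level count; default 256, or 65536 when the data
        exceed 8 bits.
    slice_index : int, optional
        Required for 3D inputs; selects an axial slice (last axis for
        NIfTI volumes).
    rgb : {"error", "luminance"}
        Color inputs raise by default; ``"luminance"`` converts with the
        ITU-R 601 weights.
    """
    path = Path(path)
    fmt = _infer_format(path, format)

    if fmt in ("png", "tiff"):
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            if rgb == "luminance":
                arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
            else:
                raise ValueError(
                    f"{path.name} is not single-channel; pass rgb='luminance' to convert"
                )
    elif fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        if arr.ndim == 3:
            if slice_index is None:
                raise ValueError(f"{path.name} is multi-frame; pass slice_index")
            arr = arr[slice_index]
    elif fmt == "nifti":
        import nibabel as nib

        vol = np.asanyarray(nib.load(path).dataobj).astype(np.float64)
        if vol.ndim == 3:
            if slice_index is None:
                raise ValueError(f"{path.name} is a 3D volume; pass slice_index")
            arr = vol[:, :, slice_index]
        elif vol.ndim == 2:
            arr = vol
        else:
            raise ValueError(f"unsupported NIfTI dimensionality {vol.ndim}")
    else:
        raise ValueError(f"unknown format {fmt!r}")

    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {arr.shape}")
    lv = _levels_for(arr, levels)
    if arr.min() < 0:
        arr = arr - arr.min()  # DICOM intercept can shift below zero
    return GrayImage(np.clip(arr, 0, lv - 1), levels=lv)


def write_gray(img: GrayImage, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a slice, quantizing half-up to 8- or 16-bit from ``levels``."""
    path = Path(path)
    fmt = _infer_format(path, format)
    quant = round_half_up(img.pixels)
    dtype = np.uint8 if img.levels <= 256 else np.uint16
    quant = np.clip(quant, 0, img.levels - 1).astype(dtype)

    if fmt in ("png", "tiff"):
        import imageio.v3 as iio

        iio.imwrite(path, quant)
    elif fmt == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(quant.astype(np.float32), affine=np.eye(4)), path)
    elif fmt == "dicom":
        raise NotImplementedError("DICOM export is out of scope; write PNG/TIFF/NIfTI")
    else:
        raise ValueError(f"unknown format {fmt!r}")
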