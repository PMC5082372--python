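"""Grayscale image container and intensity-scale helpers.

Every stage of the enhancement pipeline works on 2D grayscale slices with a
declared gray-level count ``L`` (256 for 8-bit MR exports, 4096 for 12-bit
DICOM).  Intensities are carried as floating point throughout the pipeline
and only quantized to the integer grid at write-out, so the container stores
``float64`` pixels constrained to ``[0, L - 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrayImage", "normalize_image", "round_half_up"]


@dataclass(frozen=True)
class GrayImage:
    """A 2D grayscale slice with a declared gray-level range.

    Parameters
    ----------
    pixels : ndarray
        2D array of intensities in ``[0, levels - 1]``.  Stored as float64;
        integer inputs are converted.
    levels : int
        Number of representable gray levels ``L`` (default 256).  The unit
        scale used by the fuzzy machinery divides by ``L - 1``, a global
        convention that keeps memberships comparable across sub-images.
    """

    pixels: np.ndarray
    levels: int = 256
    _skip_validation: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", arr)
        if self._skip_validation:
            return
        if arr.ndim != 2:
            raise ValueError(f"expected a 2D image, got ndim={arr.ndim}")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"image must be at least 2x2, got {arr.shape}")
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite values")
        if arr.min() < 0 or arr.max() > self.levels - 1:
            raise ValueError(
                f"pixel values [{arr.min()}, {arr.max()}] outside "
                f"[0, {self.levels - 1}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def to_unit(self) -> np.ndarray:
        """Map intensities onto [0, 1] by dividing by ``L - 1``."""
        return self.pixels / (self.levels - 1)

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        return GrayImage(pixels, levels=self.levels)


def round_half_up(values: np.ndarray) -> np.ndarray:
    """Round to the nearest integer with halves going up (0.5 -> 1).

    Used only at write-out; the pipeline itself stays continuous.
    """
    return np.floor(np.asarray(values, dtype=np.float64) + 0.5)


def normalize_image(values: np.ndarray, levels: int = 256) -> np.ndarray:
    """Linearly rescale an array onto the full gray range ``[0, L - 1]``.

    The minimum maps to 0 and the maximum to ``L - 1``.  A constant array is
    returned unchanged (degenerate guard), so an all-flat slice never divides
    by zero.
    """
    arr = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot normalize non-finite values")
    v_min = arr.min()
    v_max = arr.max()
    if v_max == v_min:
        return arr.copy()
    return (arr - v_min) / (v_max - v_min) * (levels - 1)
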