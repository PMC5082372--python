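"""Objective enhancement-quality measures.

Five measures are provided.  ``contrast_measure`` is a Michelson-type
region contrast ``|m - b| / (m + b)`` between a foreground and a background
mask — independent of the gray scale (multiplying the image by a positive
constant leaves it unchanged).  The remaining four tile the image into
``k1 x k2`` blocks of odd pixel count and average a per-block term built
from the block maximum, minimum, and (for SDME) center pixel:

=======  ================================================================
EME      20 * log10(I_max / I_min)                    (higher = more contrast)
AME      -20 * log10((I_max - I_min)/(I_max + I_min)) (decibel attenuation of
         the Michelson ratio; decreases as block contrast rises)
AMEE     -r^alpha * ln(r), r the Michelson ratio      (entropy weighting;
         non-negative, peaks at intermediate contrast)
SDME     -20 * log10(|I_max - 2 I_center + I_min| /
                      (I_max + 2 I_center + I_min))   (second-difference
         form; large for locally smooth blocks)
=======  ================================================================

Logarithms use base 10 (decibel convention) except AMEE's natural log.
Ratios and denominators are floored at a small guard before any log, so
flat blocks produce finite terms (EME of a constant image is exactly 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator
import warnings

import numpy as np

from .image import GrayImage

__all__ = [
    "MetricConfig",
    "BlockStats",
    "block_partition",
    "contrast_measure",
    "block_measure",
    "all_measures",
    "KINDS",
]

KINDS = ("eme", "ame", "amee", "sdme")


@dataclass(frozen=True)
class MetricConfig:
    """Block geometry and numeric guards for the block-based measures."""

    block_rows: int = 3
    block_cols: int = 3
    alpha: float = 1.0
    guard_epsilon: float | None = None  # defaults to 1e-4 * (L - 1)

    def __post_init__(self) -> None:
        for n in (self.block_rows, self.block_cols):
            if n < 3 or n % 2 == 0:
                raise ValueError(f"block dims must be odd and >= 3, got {n}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.guard_epsilon is not None and self.guard_epsilon <= 0:
            raise ValueError("guard_epsilon must be positive")

    def guard(self, levels: int) -> float:
        if self.guard_epsilon is not None:
            return self.guard_epsilon
        return 1e-4 * (levels - 1)


@dataclass(frozen=True)
class BlockStats:
    i_max: float
    i_min: float
    i_center: float


def _block_view(img: GrayImage, cfg: MetricConfig) -> np.ndarray:
    h, w = img.shape
    br, bc = cfg.block_rows, cfg.block_cols
    nr, nc = h // br, w // bc
    if nr < 1 or nc < 1:
        raise ValueError(
            f"image {img.shape} smaller than one {br}x{bc} block"
        )
    trimmed = img.pixels[: nr * br, : nc * bc]
    return trimmed.reshape(nr, br, nc, bc).transpose(0, 2, 1, 3)


def block_partition(img: GrayImage, cfg: MetricConfig | None = None) -> Iterator[BlockStats]:
    """Non-overlapping top-left tiling; trailing partial blocks dropped."""
    cfg = cfg or MetricConfig()
    blocks = _block_view(img, cfg)
    cr, cc = cfg.block_rows // 2, cfg.block_cols // 2
    for r in range(blocks.shape[0]):
        for c in range(blocks.shape[1]):
            b = blocks[r, c]
            yield BlockStats(
                i_max=float(b.max()), i_min=float(b.min()),
                i_center=float(b[cr, cc]),
            )


def contrast_measure(img: GrayImage, fg_mask: np.ndarray, bg_mask: np.ndarray) -> float:
    """Region contrast C = |m - b| / (m + b) between two mean gray values."""
    fg_mask = np.asarray(fg_mask, dtype=bool)
    bg_mask = np.asarray(bg_mask, dtype=bool)
    if not fg_mask.any() or not bg_mask.any():
        raise ValueError("foreground and background masks must be non-empty")
    if (fg_mask & bg_mask).any():
        raise ValueError("foreground and background masks must be disjoint")
    m = float(img.pixels[fg_mask].mean())
    b = float(img.pixels[bg_mask].mean())
    if m + b == 0.0:
        warnings.warn("both region means are zero; contrast undefined, returning 0")
        return 0.0
    return abs(m - b) / (m + b)


def block_measure(img: GrayImage, cfg: MetricConfig | None = None, kind: str = "eme") -> float:
    """Average the per-block enhancement term of the requested kind."""
    cfg = cfg or MetricConfig()
    if kind not in KINDS:
        raise ValueError(f"unknown measure kind {kind!r}; expected one of {KINDS}")
    blocks = _block_view(img, cfg)
    g = cfg.guard(img.levels)
    i_max = blocks.max(axis=(2, 3))
    i_min = blocks.min(axis=(2, 3))
    i_ctr = blocks[:, :, cfg.block_rows // 2, cfg.block_cols // 2]
    ratio_floor = g / (img.levels - 1)

    if kind == "eme":
        terms = 20.0 * np.log10(np.maximum(i_max, g) / np.maximum(i_min, g))
    elif kind == "ame":
        r = np.maximum(i_max - i_min, g) / np.maximum(i_max + i_min, g)
        terms = -20.0 * np.log10(np.clip(r, ratio_floor, 1.0))
    elif kind == "amee":
        r = np.maximum(i_max - i_min, g) / np.maximum(i_max + i_min, g)
        r = np.clip(r, ratio_floor, 1.0)
        terms = -np.power(r, cfg.alpha) * np.log(r)
    else:  # sdme
        num = np.abs(i_max - 2.0 * i_ctr + i_min)
        den = i_max + 2.0 * i_ctr + i_min
        r = np.maximum(num, g) / np.maximum(den, g)
        terms = -20.0 * np.log10(np.clip(r, ratio_floor, 1.0))
    return float(terms.mean())


def all_measures(
    img: GrayImage,
    cfg: MetricConfig | None = None,
    fg_mask: np.ndarray | None = None,
    bg_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """All block measures (plus region contrast when masks are given)."""
    out = {kind: block_measure(img, cfg, kind) for kind in KINDS}
    if fg_mask is not None and bg_mask is not None:
        out["contrast"] = contrast_measure(img, fg_mask, bg_mask)
    return out
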