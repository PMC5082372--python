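"""The NLFI filter: hemisphere split, global thresholding, and the
fuzzification -> hyperbolization -> defuzzification -> normalization chain.

A brain MR slice is split at the midline (the falx cerebri separates the
hemispheres) into left/right sub-images.  Each sub-image is partitioned into
an *object* area (bright, pixels at or above a global threshold
``th = m + e * sigma``) and a *background* area.  Each of the four
(hemisphere x area) blocks is then filtered independently:

1. fuzzify: membership = REF(u/(L-1), m_area/(L-1)) — pixels near the area's
   mean gray value get membership near 1, distant pixels near 0;
2. hyperbolize: min-max rescale the memberships and pass them through a
   strictly increasing transform g with g(0)=0, g(1)=1, widening the spread
   around the mean;
3. defuzzify: map memberships back to the sub-image's original gray range.

The four per-area chains are independent; running them sequentially or
concurrently produces bit-identical output.  The reassembled image is
finally min-max normalized onto [0, L-1].
"""

from __future__ import annotations

import logging
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .ifs import REFParams, ref_eval
from .image import GrayImage, normalize_image

__all__ = [
    "ThresholdParams",
    "RegionPartition",
    "MembershipPlane",
    "NLFIConfig",
    "split_midline",
    "global_threshold",
    "partition_object_background",
    "fuzzify_area",
    "hyperbolize_area",
    "defuzzify_area",
    "nlfi_filter",
]

logger = logging.getLogger(__name__)

Area = Literal["object", "background"]


class DegenerateAreaError(ValueError):
    """Raised when an object/background area selected for filtering is empty."""


@dataclass(frozen=True)
class ThresholdParams:
    """Per-hemisphere threshold offsets: th_k = mean_k + e_k * sigma_k."""

    e1: float = 0.1
    e2: float = 0.1

    def __post_init__(self) -> None:
        if self.e1 < 0 or self.e2 < 0:
            raise ValueError(f"e must be non-negative, got ({self.e1}, {self.e2})")

    def for_hemisphere(self, k: int) -> float:
        return self.e1 if k == 1 else self.e2


@dataclass(frozen=True)
class RegionPartition:
    """Object/background split of one hemisphere sub-image."""

    k: int
    object_mask: np.ndarray
    background_mask: np.ndarray
    th: float
    m_obj: float
    m_bkg: float
    degenerate: bool = False


@dataclass(frozen=True)
class MembershipPlane:
    """Membership degrees of one area's pixels (flat, mask-ordered)."""

    values: np.ndarray
    mu_min: float
    mu_max: float


def hyperbolic_transform(t: np.ndarray) -> np.ndarray:
    """Default hyperbolization body g(t) = (e^t - 1)/(e - 1)."""
    return (np.exp(t) - 1.0) / (np.e - 1.0)


# Named, pluggable hyperbolization transforms (strictly increasing on [0,1],
# fixing 0 and 1).  A transcribed closed form can be registered here without
# touching the chain.
HYPERBOLIZATION_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "exp": hyperbolic_transform,
    "identity": lambda t: t,
}


@dataclass(frozen=True)
class NLFIConfig:
    """Everything the filter chain needs beyond the image itself."""

    thresholds: ThresholdParams = field(default_factory=ThresholdParams)
    ref: REFParams = field(default_factory=REFParams)
    object_transform: str = "exp"
    background_transform: str = "exp"
    parallel: bool = False

    def transform(self, area: Area) -> Callable[[np.ndarray], np.ndarray]:
        name = self.object_transform if area == "object" else self.background_transform
        try:
            return HYPERBOLIZATION_TRANSFORMS[name]
        except KeyError:
            raise ValueError(f"unknown hyperbolization transform {name!r}") from None


def split_midline(img: GrayImage) -> tuple[GrayImage, GrayImage]:
    """Split at the vertical midline into (left, right) hemisphere views.

    For odd width the extra column goes to the left half.  The halves are
    views onto the parent pixel buffer.
    """
    w = img.shape[1]
    if w < 2:
        raise ValueError(f"image width must be >= 2, got {w}")
    split = (w + 1) // 2
    left = GrayImage(img.pixels[:, :split], levels=img.levels, _skip_validation=True)
    right = GrayImage(img.pixels[:, split:], levels=img.levels, _skip_validation=True)
    return left, right


def global_threshold(sub: GrayImage, e: float) -> float:
    """th = mean + e * population standard deviation of the sub-image.

    Clamped to the sub-image's own gray range so the threshold always lies
    among realizable values.
    """
    if e < 0:
        raise ValueError(f"e must be non-negative, got {e}")
    vals = sub.pixels
    th = float(vals.mean() + e * vals.std())
    return float(np.clip(th, vals.min(), vals.max()))


def partition_object_background(sub: GrayImage, th: float, k: int = 1) -> RegionPartition:
    """Split a sub-image at th: object = {u >= th}, background = {u < th}.

    An empty area flags the partition degenerate (boundary thresholds);
    callers pass the affected area through unchanged rather than failing.
    """
    obj = sub.pixels >= th
    bkg = ~obj
    n_obj = int(obj.sum())
    n_bkg = int(bkg.sum())
    degenerate = n_obj == 0 or n_bkg == 0
    m_obj = float(sub.pixels[obj].mean()) if n_obj else float("nan")
    m_bkg = float(sub.pixels[bkg].mean()) if n_bkg else float("nan")
    return RegionPartition(
        k=k, object_mask=obj, background_mask=bkg, th=th,
        m_obj=m_obj, m_bkg=m_bkg, degenerate=degenerate,
    )


def _area_mask(part: RegionPartition, area: Area) -> np.ndarray:
    return part.object_mask if area == "object" else part.background_mask


def fuzzify_area(
    sub: GrayImage, part: RegionPartition, area: Area, ref: REFParams | None = None
) -> MembershipPlane:
    """Membership of each area pixel: REF of its unit gray vs the area mean.

    Gray values are unit-scaled by L-1 (the global convention), so a pixel
    sitting exactly at the area's mean gets membership 1.
    """
    mask = _area_mask(part, area)
    if not mask.any():
        raise DegenerateAreaError(f"{area} area of hemisphere {part.k} is empty")
    u = sub.pixels[mask] / (sub.levels - 1)
    m = (part.m_obj if area == "object" else part.m_bkg) / (sub.levels - 1)
    mu = np.asarray(ref_eval(u, np.full_like(u, m), ref))
    return MembershipPlane(values=mu, mu_min=float(mu.min()), mu_max=float(mu.max()))


def hyperbolize_area(
    mu: MembershipPlane,
    transform: Callable[[np.ndarray], np.ndarray] = hyperbolic_transform,
) -> MembershipPlane:
    """Min-max rescale the memberships, then apply the hyperbolic transform.

    ``t = (mu - mu_min)/(mu_max - mu_min)`` and the output is ``g(t)`` with g
    strictly increasing, g(0)=0, g(1)=1.  A flat plane (mu_max == mu_min) is
    returned unchanged.
    """
    if mu.mu_max <= mu.mu_min:
        return mu
    t = (mu.values - mu.mu_min) / (mu.mu_max - mu.mu_min)
    out = np.clip(transform(t), 0.0, 1.0)
    return MembershipPlane(values=out, mu_min=float(out.min()), mu_max=float(out.max()))


def defuzzify_area(
    mu_prime: MembershipPlane, gray_min: float, gray_max: float
) -> np.ndarray:
    """Map memberships back to gray values: u' = g_min + (g_max - g_min) * mu'."""
    if gray_min > gray_max:
        raise ValueError(f"gray_min {gray_min} > gray_max {gray_max}")
    vals = mu_prime.values
    if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
        raise ValueError("memberships outside [0, 1]")
    return gray_min + (gray_max - gray_min) * vals


def _filter_one_area(
    sub: GrayImage, part: RegionPartition, area: Area, config: NLFIConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Run the 3-stage chain on one area; returns (mask, filtered values)."""
    mask = _area_mask(part, area)
    mu = fuzzify_area(sub, part, area, config.ref)
    if mu.mu_max <= mu.mu_min:
        # flat membership (constant area): degenerate pass-through
        return mask, sub.pixels[mask]
    mu_prime = hyperbolize_area(mu, config.transform(area))
    gray = defuzzify_area(
        mu_prime, float(sub.pixels.min()), float(sub.pixels.max())
    )
    return mask, gray


def _filter_sub_image(sub: GrayImage, k: int, config: NLFIConfig) -> np.ndarray:
    e = config.thresholds.for_hemisphere(k)
    th = global_threshold(sub, e)
    part = partition_object_background(sub, th, k=k)
    out = np.empty_like(sub.pixels)

    areas: list[Area] = ["object", "background"]
    jobs = []
    for area in areas:
        if not _area_mask(part, area).any():
            msg = (
                f"hemisphere {k}: empty {area} area at th={th:.3f}; "
                "passing the sub-image through unchanged for that area"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=3)
            continue
        jobs.append(area)

    if config.parallel and len(jobs) > 1:
        with ThreadPoolExecutor(max_workers=len(jobs)) as pool:
            results = list(
                pool.map(lambda a: _filter_one_area(sub, part, a, config), jobs)
            )
    else:
        results = [_filter_one_area(sub, part, area, config) for area in jobs]

    covered = np.zeros(sub.shape, dtype=bool)
    for mask, gray in results:
        out[mask] = gray
        covered |= mask
    out[~covered] = sub.pixels[~covered]  # degenerate pass-through
    return out


def nlfi_filter(img: GrayImage, config: NLFIConfig | None = None) -> GrayImage:
    """Full NLFI chain: split, per-area filter, reassemble, normalize.

    Deterministic; the four per-area chains are independent and may run
    concurrently (``config.parallel``) with bit-identical output.  The
    result lies in ``[0, L - 1]``.
    """
    if config is None:
        config = NLFIConfig()
    left, right = split_midline(img)
    out = np.empty_like(img.pixels)
    split = left.shape[1]
    out[:, :split] = _filter_sub_image(left, 1, config)
    out[:, split:] = _filter_sub_image(right, 2, config)
    return GrayImage(normalize_image(out, img.levels), levels=img.levels)
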