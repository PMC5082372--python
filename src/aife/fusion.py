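"""Nonlinear fusion of the three NLFI-filtered MR modalities.

The enhancement scheme filters T1-weighted, contrast-enhanced T1-weighted
and T2-FLAIR slices independently, then combines them pointwise into a
single display image.  The default composition is

    E = normalize( a1 * X_t1  +  b1 * (X_t1c (*) X_flair)
                   + a2 * X_t1c  +  c1 * X_flair )

where ``(*)`` is elementwise multiplication on unit-scaled intensities (so
products stay on the gray scale) and a1, a2, b1, c1 are scaling factors.
The anatomical reading: T1 carries structure, the T1c x FLAIR product
highlights voxels that are bright in *both* pathology-sensitive channels
(enhancing rim inside edema), and the a2/c1 terms blend the two pathology
channels — their sum is constrained to 1 so the blend is a convex average.
A "logical" composition replacing the product by elementwise max (OR-like)
or min (AND-like) is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import GrayImage, normalize_image

__all__ = ["MultiModalStack", "FusionParams", "validate_fusion_params", "aife_fuse"]


@dataclass(frozen=True)
class MultiModalStack:
    """Co-registered, same-shape T1 / contrast-T1 / T2-FLAIR slices."""

    t1: GrayImage
    t1c: GrayImage
    flair: GrayImage

    def __post_init__(self) -> None:
        shapes = {self.t1.shape, self.t1c.shape, self.flair.shape}
        if len(shapes) != 1:
            raise ValueError(f"modality shapes differ: {shapes}")
        levels = {self.t1.levels, self.t1c.levels, self.flair.levels}
        if len(levels) != 1:
            raise ValueError(f"modality gray-level counts differ: {levels}")

    @property
    def levels(self) -> int:
        return self.t1.levels

    @property
    def shape(self) -> tuple[int, int]:
        return self.t1.shape


@dataclass(frozen=True)
class FusionParams:
    """Scaling factors and composition choice for the fusion stage.

    When ``strict_constraint`` is set (the default), a2 + c1 must equal 1:
    the two pathology channels enter as a convex combination.
    """

    a1: float = 1.0
    a2: float = 0.5
    b1: float = 1.0
    c1: float = 0.5
    strict_constraint: bool = True
    logical_op: str = "max"
    expression: str = "product"  # "product" | "logical"


def validate_fusion_params(p: FusionParams) -> FusionParams:
    """Validate scaling factors; raises on a violated constraint."""
    for name in ("a1", "a2", "b1", "c1"):
        v = getattr(p, name)
        if not np.isfinite(v):
            raise ValueError(f"scaling factor {name} is not finite: {v}")
    if p.strict_constraint and abs(p.a2 + p.c1 - 1.0) > 1e-9:
        raise ValueError(
            f"fusion constraint violated: a2 + c1 = {p.a2 + p.c1} != 1"
        )
    if p.logical_op not in ("max", "min"):
        raise ValueError(f"logical_op must be 'max' or 'min', got {p.logical_op!r}")
    if p.expression not in ("product", "logical"):
        raise ValueError(f"expression must be 'product' or 'logical', got {p.expression!r}")
    return p


def aife_fuse(filtered: MultiModalStack, params: FusionParams | None = None) -> GrayImage:
    """Fuse three filtered modality images into one enhanced image.

    Pointwise combination on unit-scaled intensities followed by min-max
    normalization back onto [0, L - 1].  Deterministic; output shape and
    gray range equal the inputs'.
    """
    if params is None:
        params = FusionParams()
    params = validate_fusion_params(params)

    x1 = filtered.t1.to_unit()
    x2 = filtered.t1c.to_unit()
    x3 = filtered.flair.to_unit()

    if params.expression == "product":
        cross = x2 * x3
    else:
        cross = np.maximum(x2, x3) if params.logical_op == "max" else np.minimum(x2, x3)

    fused = params.a1 * x1 + params.b1 * cross + params.a2 * x2 + params.c1 * x3
    return GrayImage(normalize_image(fused, filtered.levels), levels=filtered.levels)
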