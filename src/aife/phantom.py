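"""Synthetic multi-modal brain phantom.

Clinical brain-tumor MR data are private, so tests and examples run on a
generated head phantom: an elliptical head with left/right hemispheres
around a vertical midline, a gray-matter cortical band around a white-matter
interior, two symmetric CSF ventricles, and a nested lesion — tumor core,
contrast-enhancing rim, surrounding vasogenic edema — placed in one
hemisphere.  Per-modality tissue contrasts follow the familiar appearances:

- T1-weighted: white > gray matter, CSF dark, lesion (edema/core) darker
  than white matter;
- contrast-enhanced T1: as T1 but the tumor rim enhances brightly
  (gadolinium leaks through the disrupted blood-brain barrier);
- T2-FLAIR: edema bright, free-water (CSF) signal suppressed.

Magnitude-MR noise is Rician: each clean value v becomes
``sqrt((v + n1)^2 + n2^2)`` with n1, n2 independent zero-mean Gaussians.
Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fusion import MultiModalStack
from .image import GrayImage

__all__ = [
    "TISSUES",
    "PhantomSpec",
    "generate_phantom",
    "add_rician_noise",
    "reference_phantom_spec",
    "lesion_masks",
]

# label codes
TISSUES = {
    "background": 0,
    "csf": 1,
    "gray_matter": 2,
    "white_matter": 3,
    "edema": 4,
    "tumor_rim": 5,
    "tumor_core": 6,
}

# Mean intensities (L = 256) per tissue x modality, mimicking the standard
# modality appearances; fully overridable through PhantomSpec.tissue_table.
DEFAULT_TISSUE_TABLE: dict[str, dict[str, float]] = {
    "background":   {"t1": 0.0,   "t1c": 0.0,   "flair": 0.0},
    "csf":          {"t1": 40.0,  "t1c": 40.0,  "flair": 30.0},
    "gray_matter":  {"t1": 120.0, "t1c": 120.0, "flair": 140.0},
    "white_matter": {"t1": 160.0, "t1c": 160.0, "flair": 130.0},
    "edema":        {"t1": 70.0,  "t1c": 75.0,  "flair": 220.0},
    "tumor_rim":    {"t1": 90.0,  "t1c": 230.0, "flair": 180.0},
    "tumor_core":   {"t1": 60.0,  "t1c": 60.0,  "flair": 160.0},
}

MODALITIES = ("t1", "t1c", "flair")


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of the synthetic head phantom."""

    height: int = 128
    width: int = 128
    seed: int = 0
    levels: int = 256
    tissue_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TISSUE_TABLE.items()}
    )
    tumor_center: tuple[float, float] | None = None  # (row, col); None = auto
    tumor_core_radius: float = 5.0
    tumor_radius: float = 9.0       # outer radius of the enhancing rim
    edema_radius: float = 16.0
    noise_sigma: float = 5.0
    with_tumor: bool = True

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("phantom must be at least 16x16")
        if not 0.0 <= self.tumor_core_radius < self.tumor_radius < self.edema_radius:
            raise ValueError(
                "need core_radius < tumor_radius < edema_radius, got "
                f"{self.tumor_core_radius}, {self.tumor_radius}, {self.edema_radius}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        missing = set(TISSUES) - set(self.tissue_table)
        if missing:
            raise ValueError(f"tissue_table missing classes: {sorted(missing)}")

    def resolved_tumor_center(self) -> tuple[float, float]:
        if self.tumor_center is not None:
            return self.tumor_center
        # default: mid-height, centred in the right hemisphere
        return (self.height * 0.45, self.width * 0.68)


def _head_geometry(spec: PhantomSpec) -> np.ndarray:
    """Build the label map (no noise, no intensities)."""
    h, w = spec.height, spec.width
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.45 * h, 0.40 * w
    head = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
    brain = ((rows - cy) / (0.88 * ry)) ** 2 + ((cols - cx) / (0.85 * rx)) ** 2 <= 1.0

    labels = np.zeros((h, w), dtype=np.int64)
    labels[head] = TISSUES["gray_matter"]          # cortical band = head minus brain core
    labels[brain] = TISSUES["white_matter"]

    # two midline-symmetric ventricles (CSF), small ellipses near the centre
    for sign in (-1.0, 1.0):
        vc = cx + sign * 0.14 * w
        vent = ((rows - cy) / (0.14 * h)) ** 2 + ((cols - vc) / (0.05 * w)) ** 2 <= 1.0
        labels[vent & brain] = TISSUES["csf"]

    if spec.with_tumor:
        ty, tx = spec.resolved_tumor_center()
        r2 = (rows - ty) ** 2 + (cols - tx) ** 2
        if not brain[int(round(ty)), int(round(tx))]:
            raise ValueError("tumor centre lies outside the brain")
        edema = (r2 <= spec.edema_radius ** 2) & brain
        rim = (r2 <= spec.tumor_radius ** 2) & brain
        core = (r2 <= spec.tumor_core_radius ** 2) & brain
        labels[edema] = TISSUES["edema"]
        labels[rim] = TISSUES["tumor_rim"]
        labels[core] = TISSUES["tumor_core"]
    return labels


def add_rician_noise(img: GrayImage, sigma: float, seed: int) -> GrayImage:
    """Rician-corrupt an image: v -> sqrt((v + n1)^2 + n2^2), clipped.

    n1, n2 are independent zero-mean Gaussians with standard deviation
    sigma.  sigma = 0 returns the image unchanged.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return img
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=img.shape)
    n2 = rng.normal(0.0, sigma, size=img.shape)
    noisy = np.hypot(img.pixels + n1, n2)
    return GrayImage(np.clip(noisy, 0.0, img.levels - 1), levels=img.levels)


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[MultiModalStack, np.ndarray]:
    """Generate the co-registered three-modality stack and its label map.

    Returns ``(stack, labels)`` where ``labels`` holds the integer tissue
    code of every pixel (see ``TISSUES``).  Deterministic given the spec's
    seed; each modality gets an independent noise realization.
    """
    spec = spec or PhantomSpec()
    labels = _head_geometry(spec)
    images = {}
    for i, modality in enumerate(MODALITIES):
        clean = np.zeros(labels.shape, dtype=np.float64)
        for tissue, code in TISSUES.items():
            clean[labels == code] = spec.tissue_table[tissue][modality]
        img = GrayImage(clean, levels=spec.levels)
        # distinct but reproducible stream per modality
        images[modality] = add_rician_noise(img, spec.noise_sigma, spec.seed * 3 + i)
    return MultiModalStack(**images), labels


def lesion_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(foreground, background) masks: lesion vs normal brain tissue.

    Foreground is the whole lesion (edema + rim + core); background is
    normal gray + white matter.  Used as the ground-truth stand-in for an
    expert's object outline when computing region contrast.
    """
    fg = np.isin(labels, [TISSUES["edema"], TISSUES["tumor_rim"], TISSUES["tumor_core"]])
    bg = np.isin(labels, [TISSUES["gray_matter"], TISSUES["white_matter"]])
    return fg, bg


def reference_phantom_spec(seed: int = 7) -> PhantomSpec:
    """The fixed regression phantom used across the test-suite and examples."""
    return PhantomSpec(height=128, width=128, seed=seed)
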