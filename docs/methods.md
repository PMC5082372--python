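# Methods

## Model and procedure

The package enhances 2D axial brain MR slices in two stages: a
per-modality intuitionistic-fuzzy filter, then pointwise fusion of the
three filtered modalities (T1, contrast-enhanced T1, T2-FLAIR) into one
display image. Both stages are deterministic; the only randomness in the
package lives in the synthetic phantom and its noise model.

### Restricted equivalence functions

A REF is a symmetric similarity on `[0,1]²` equal to 1 exactly on the
diagonal and 0 exactly at `{0,1}`. It is composed from two increasing
automorphisms of the unit interval:

    REF(x, y) = φ_out⁻¹(1 − |φ_in(x) − φ_in(y)|)

Defaults: `φ_out(x) = log((e−1)x + 1)` and `φ_in(x) = x²`, giving
`REF(x,y) = (e^{1−|x²−y²|} − 1)/(e − 1)`. The classical exponential REF is
the `φ_in = identity` special case; its commonly quoted scale constant
0.582 is a 3-decimal rounding of the exact `1/(e−1) = 0.58198…`, and
`chaira_ref` uses the exact constant by default (the rounded one is
selectable) so that it coincides with the generic construction to machine
precision. The quadratic inner automorphism is the point of the design:
two regions whose gray values have the same spread but different means
receive identical membership profiles under the identity-inner REF
(divergence exactly zero) but remain distinguishable under the quadratic
one.

### Intuitionistic fuzzy sets and divergence

Non-membership is derived from membership through a fuzzy-complement
generator — Sugeno `ν = (1−μ)/(1+εμ)` by default, Yager selectable — with
`ε ∈ [0,1]` and hesitation `π = 1 − μ − ν`. The divergence between two
IFS planes is the exponential divergence

    d(a, b) = 2 − (1 − a + b)e^{a−b} − (1 − b + a)e^{b−a}

evaluated on hesitation-weighted effective memberships `μ + w·π`, summed
and divided by the element count (the normalizer is configurable). The
weight defaults to `w = 0.6`; the kernel is pluggable. `ε` defaults to
0.2 — the divergence analysis only needs a fixed, nonzero hesitation
scale, and its qualitative conclusions (zero vs positive) do not depend
on the choice.

### The filter chain

Hemisphere split at the geometric vertical midline, the extra column of
an odd-width slice going to the left half; anatomical midline detection
is deliberately not attempted. Threshold `th = m + e·σ` per hemisphere
with the *population* standard deviation, clamped to the sub-image's
gray range; pixels equal to the threshold count as object. Defaults
`e₁ = e₂ = 0.1`, a mild offset that keeps both areas populated on
brain-like histograms.

Per area: membership against the area's own mean (gray values unit-scaled
by `L−1` globally, never by a per-image maximum, so memberships are
comparable across sub-images); min–max rescale and the hyperbolic
transform `g(t) = (e^t − 1)/(e − 1)` (strictly increasing, `g(0)=0`,
`g(1)=1`, registered by name so alternative closed forms drop in without
API changes); linear defuzzification onto the sub-image's original
`[u_min, u_max]`. The filtered slice is min–max normalized onto
`[0, L−1]` as a whole (not per hemisphere).

Degenerate inputs degrade gracefully rather than erroring: an empty
object or background area (threshold at a gray-range boundary) and a flat
membership plane (constant area) both pass the affected pixels through
unchanged, with a warning. A constant slice is therefore a fixed point of
the whole chain. Values stay continuous through the pipeline; quantization
(round half-up, 8- or 16-bit from `L`) happens only on file write, and all
quality measures run on the continuous values.

### Fusion

`E = normalize(a1·X_t1 + b1·(X_t1c ⊙ X_flair) + a2·X_t1c + c1·X_flair)`
on unit-scaled intensities, so the product term cannot blow past the gray
scale. Defaults `a1 = b1 = 1`, `a2 = c1 = 0.5`, with `a2 + c1 = 1`
enforced (strictly by default): the two pathology channels enter as a
convex blend. "Logical" composition replaces the product by elementwise
max (OR-like) or min (AND-like). The composition is a named, configurable
expression; the shipped default reflects the block-diagram reading —
anatomy plus a coincidence term for rim-inside-edema plus the blended
pathology channels.

### Quality measures

Region contrast `C = |m − b|/(m + b)` over user-supplied disjoint masks;
scale-invariant by construction. Block measures tile the image with
non-overlapping odd-sized blocks from the top-left, dropping trailing
partial blocks, and average a per-block term:

- EME `20·log10(I_max/I_min)`
- AME `−20·log10((I_max−I_min)/(I_max+I_min))`
- AMEE `−r^α·ln r`, `r` the Michelson ratio, `α` default 1 (sign chosen
  to keep the measure non-negative)
- SDME `−20·log10(|I_max − 2I_c + I_min|/(I_max + 2I_c + I_min))` with
  `I_c` the block's center pixel

Base-10 logs (decibel convention, switchable only by editing the measure —
deliberately not a knob). Guards: `I_min` and all denominators floored at
`1e−4·(L−1)` before logs, and ratios clipped to `[1e−4, 1]`, so flat
blocks yield finite terms and a constant image has EME exactly 0.

Orientation: EME grows with per-block dynamic range, while AME and SDME —
decibel attenuations of ratios in `(0,1]` — *shrink* as local contrast
rises, and AMEE peaks at `r = e^{−1/α}`. The four measures are therefore
reported in their standard forms rather than forced onto a single
higher-is-better axis; comparisons between an original and an enhanced
image should read each measure in its own direction.

## The phantom

The phantom emulates one axial slice: elliptical head, gray-matter
cortical band around white matter, two midline-symmetric CSF ventricles,
and a nested lesion (tumor core r=5 px, enhancing rim to r=9 px, edema to
r=16 px on the 128×128 default) in the right hemisphere. Default tissue
means (L=256) follow the standard modality appearances — on T1: WM 160,
GM 120, CSF 40, edema 70, rim 90, core 60; contrast-T1 is T1 with the rim
enhanced to 230; FLAIR: edema 220 bright, CSF 30 suppressed, WM 130,
GM 140, rim 180, core 160. Noise is Rician,
`v → sqrt((v+n₁)² + n₂²)` with independent zero-mean Gaussians of
σ = 5 gray levels (SNR ≈ 25–45 for brain tissue, a typical clinical
magnitude-image regime), clipped to the gray range; each modality draws
an independent, seed-derived realization.

What the phantom does *not* model: realistic cortical folding, partial
volume, bias fields, 3D structure, or registration error. Passing tests
therefore demonstrate the pipeline's contracts and the direction of its
contrast effect on piecewise-homogeneous, co-registered data — not
clinical-grade performance on real MRI.

## Problem sizes and defaults in tests

The test-suite and the reproduction script run on 128×128 phantoms
(64×64 for CLI round-trips), nine independent phantom seeds for the
fusion trend, 10⁴ random pairs for the REF axiom sweep, 100 random 32×32
images for the measure/oracle equivalence, and ~10⁵ samples for the
Rician moment check — sizes at which every quantity is stable to well
inside the asserted tolerances while the whole suite runs in seconds.

## Known limitations

- The midline split assumes a roughly centred, unrotated head; a shifted
  falx (mass effect) misallocates columns between hemispheres.
- The fusion expression is a configurable family; only the shipped
  default and the logical variants are exercised by tests.
- DICOM support is read-only (stored values × slope + intercept); no
  window/level is ever applied, by design.
- The filter is intensity-based and 2D; volumetric consistency across
  slices is out of scope.
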