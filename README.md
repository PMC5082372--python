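# aife — adaptive intuitionistic fuzzy enhancement of brain-tumor MRI

Brain-tumor reading works across several MR sequences at once: T1-weighted
slices show anatomy, contrast-enhanced T1 shows the enhancing tumor rim,
and T2-FLAIR shows the surrounding edema with free water suppressed.
Low-grade lesions are often nearly isointense with healthy tissue on any
single sequence, so radiologists flip between images to piece the picture
together. This package implements an enhancement scheme that (1) raises
the contrast of each modality with an intuitionistic-fuzzy filter and
(2) fuses the three filtered slices into a single display image in which
normal structures and the lesion are visible simultaneously.

## Method

**Per-modality fuzzy filter (NLFI).** A slice is split at the vertical
midline (the falx cerebri) into hemisphere sub-images. Each sub-image is
thresholded at `th = m + e·σ` (mean plus a non-negative multiple of the
standard deviation) into a bright *object* area and a *background* area.
Each of the four (hemisphere × area) blocks then passes through

1. *fuzzification* — membership `μ_ij = REF(u_ij/(L−1), m_area/(L−1))`
   using a restricted equivalence function (REF) built from automorphisms
   of the unit interval,

   `REF(x, y) = (e^{1−|x²−y²|} − 1)/(e − 1)`,

   so a pixel at its area's mean gray value has membership 1. The
   quadratic inner automorphism makes the similarity sensitive to *where*
   on the gray scale a difference sits — unlike the classical
   `(e^{1−|x−y|} − 1)/(e − 1)`, which assigns mean-shifted regions
   identical membership profiles (their intuitionistic fuzzy divergence
   collapses to zero; see `examples/ref_discriminability.py`);
2. *hyperbolization* — min–max rescaling of the memberships followed by
   the strictly increasing transform `g(t) = (e^t − 1)/(e − 1)`;
3. *defuzzification* — linear mapping back onto the sub-image's original
   gray range.

The reassembled slice is min–max normalized onto `[0, L−1]`. The four
per-area chains are independent and can run concurrently with
bit-identical results.

**Fusion.** The three filtered modalities `X_t1, X_t1c, X_flair`
(unit-scaled) combine pointwise as

`E = normalize( a1·X_t1 + b1·(X_t1c ⊙ X_flair) + a2·X_t1c + c1·X_flair )`

with scaling factors `a1 = b1 = 1`, `a2 = c1 = 0.5` and the constraint
`a2 + c1 = 1` (convex blend of the two pathology channels). The product
term highlights pixels bright in *both* pathology-sensitive channels —
the enhancing rim inside edema. An elementwise max/min ("logical")
composition is selectable.

**Quality measures.** Region contrast `C = |m − b|/(m + b)` between a
foreground and a background mask, plus the block-based measures EME, AME,
AMEE and SDME averaged over odd-sized (default 3×3) tiles.

**Phantom.** Clinical data being private, a synthetic head phantom with
ground-truth tissue labels (cortex, white matter, CSF ventricles, tumor
core / enhancing rim / edema, Rician noise) supplies reproducible inputs.

## Worked example

```sh
python examples/fuse_and_measure.py
```

prints (reference phantom, seed 7):

```
raw T1 lesion contrast:    0.3367
fused image lesion contrast: 0.5592

block measures of the fused image (3x3 blocks):
  eme     3.9517
  ame    19.8464
  amee    0.2243
  sdme   33.4350
```

The lesion/normal-brain contrast of the fused image (0.56) well exceeds
that of the raw T1 input (0.34): the fused single image separates the
lesion from healthy tissue better than the anatomy scan alone. The block
measures quantify local contrast structure of the fused result (EME grows
with per-block dynamic range; AME/SDME are decibel attenuations of
Michelson-type ratios; AMEE is entropy-weighted).

The same pipeline is scriptable from a shell:

```sh
aife phantom --size 128 --seed 7 --out-dir scratch/phantom
aife enhance -i scratch/phantom/flair.png -o scratch/flair_enh.png --e1 0.1 --e2 0.1
aife fuse --t1 scratch/phantom/t1.png --t1c scratch/phantom/t1c.png \
          --flair scratch/phantom/flair.png -o scratch/fused.png
aife measure -i scratch/fused.png --all --block 3
```

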