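"""The full scheme: filter three modalities, fuse, and measure quality.

Each modality is filtered independently, then combined pointwise:
E = normalize(a1*T1 + b1*(T1c x FLAIR) + a2*T1c + c1*FLAIR) with
a2 + c1 = 1.  Block-based enhancement measures of the fused image are
printed alongside the lesion contrast of the raw T1 input.
"""

from aife import (
    FusionParams,
    MultiModalStack,
    aife_fuse,
    all_measures,
    contrast_measure,
    generate_phantom,
    nlfi_filter,
)
from aife.phantom import lesion_masks, reference_phantom_spec

stack, labels = generate_phantom(reference_phantom_spec(seed=7))
fg, bg = lesion_masks(labels)

filtered = MultiModalStack(
    t1=nlfi_filter(stack.t1),
    t1c=nlfi_filter(stack.t1c),
    flair=nlfi_filter(stack.flair),
)
fused = aife_fuse(filtered, FusionParams(a1=1.0, b1=1.0, a2=0.5, c1=0.5))

print(f"raw T1 lesion contrast:    {contrast_measure(stack.t1, fg, bg):.4f}")
print(f"fused image lesion contrast: {contrast_measure(fused, fg, bg):.4f}")
print("\nblock measures of the fused image (3x3 blocks):")
for kind, value in all_measures(fused).items():
    print(f"  {kind:5s} {value:8.4f}")
print(
    "\nEME grows with per-block dynamic range; AME and SDME are decibel\n"
    "attenuations of Michelson-type ratios (they shrink as local contrast\n"
    "rises); AMEE weights the Michelson ratio by its entropy."
)
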