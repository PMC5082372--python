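"""Fuzzy filtering of one modality: lesion contrast before and after.

Generates the reference phantom, runs the per-area fuzzy filter chain on
the T2-FLAIR channel (where edema is bright), and compares the
Michelson-type contrast between the lesion and normal brain tissue using
the phantom's ground-truth labels.
"""

from aife import contrast_measure, generate_phantom, nlfi_filter
from aife.phantom import lesion_masks, reference_phantom_spec

stack, labels = generate_phantom(reference_phantom_spec(seed=7))
fg, bg = lesion_masks(labels)

flair = stack.flair
filtered = nlfi_filter(flair)

before = contrast_measure(flair, fg, bg)
after = contrast_measure(filtered, fg, bg)
print(f"T2-FLAIR lesion/normal contrast before filtering: {before:.4f}")
print(f"T2-FLAIR lesion/normal contrast after filtering:  {after:.4f}")
print(
    "\nThe contrast C = |m - b| / (m + b) compares mean gray values of the\n"
    "lesion (edema + rim + core) and normal gray/white matter; a higher\n"
    "value after filtering means the lesion stands out more."
)
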