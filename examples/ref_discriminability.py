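"""Why the quadratic-inner REF: discriminating mean-shifted regions.

Two 9-element regions share the same spread of gray values around their
means (one centred at 0.35, one at 0.65).  Memberships computed against
each region's own mean look identical to a similarity that only sees
|x - y| (the classical exponential REF), so the intuitionistic fuzzy
divergence between the regions collapses to zero.  The quadratic inner
automorphism keeps the absolute gray level in play and the regions stay
distinguishable.
"""

import numpy as np

from aife import build_ifs, chaira_ref, ifs_divergence, ref_eval
from aife.ifs import REFParams

offsets = np.linspace(-0.12, 0.12, 9)
part_a = 0.35 + offsets
part_b = 0.65 + offsets


def divergence(ref_params):
    def memberships(part):
        mean = np.full_like(part, part.mean())
        if ref_params is None:
            return np.asarray(chaira_ref(part, mean))
        return np.asarray(ref_eval(part, mean, ref_params))

    a = build_ifs(memberships(part_a), epsilon=0.2)
    b = build_ifs(memberships(part_b), epsilon=0.2)
    return ifs_divergence(a, b, param=0.6)


print(f"classical REF divergence:  {divergence(None):.6f}")
print(f"quadratic REF divergence:  {divergence(REFParams()):.6f}")
print(
    "\nA zero divergence means the membership planes cannot tell the two\n"
    "regions apart even though their gray levels differ by 0.3; the\n"
    "positive value shows the quadratic-inner REF preserves the contrast."
)
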