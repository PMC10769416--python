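"""Tiny constructors shared across test modules."""

import numpy as np

from hybridscape import AncestryCallSet


def toy_calls(pos, hard, minor_parent=1, chrom="chr1"):
    """Call set with degenerate posteriors matching the given hard calls
    (minor dosage, -1 missing)."""
    hard = np.asarray(hard, dtype=np.int8)
    state = np.where(hard < 0, 0, hard if minor_parent == 1 else 2 - hard)
    post = np.zeros((*hard.shape, 3))
    for k in range(3):
        post[..., k] = state == k
    return AncestryCallSet(np.full(len(pos), chrom), np.asarray(pos), post, hard, minor_parent)
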