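"""Detect a CRISPR direct-repeat/spacer array.

Plants a 29 bp direct repeat with 12 random spacers into a random genome and
runs the array detector, which reports 1-based coordinates, the repeat and
spacer inventory, and the per-column majority consensus of the repeat.
"""

import numpy as np

from diffpick import find_arrays
from diffpick.crispr import _identity

rng = np.random.default_rng(11)
bases = np.array(list("ACGT"))
rand = lambda n: "".join(bases[rng.integers(0, 4, size=n)])

repeat = rand(29)
spacers = []
while len(spacers) < 12:
    cand = rand(34)
    if all(_identity(cand, s) < 0.5 for s in spacers):
        spacers.append(cand)
genome = rand(8000) + repeat + "".join(s + repeat for s in spacers) + rand(8000)

(array,) = find_arrays(genome)
print(f"array at {array.start:,}-{array.end:,} bp (1-based, forward strand)")
print(f"repeat copies: {len(array.repeats)}   spacers: {array.n_spacers}")
print(f"consensus repeat ({len(array.consensus_repeat)} bp): {array.consensus_repeat}")
print("recovered repeat matches the planted one:", array.consensus_repeat == repeat)
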