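"""Build a gold-standard squiggle from a sequence and a k-mer pore model.

The gold standard is the noise-free step-current signal a perfect
sequencer would produce: one event per k-mer window of the sequence.
"""

import numpy as np

import squigglesim as sq

# A synthetic pore model + reference sequence (deterministic from the seed).
model, gold = sq.make_fixture(seed=1, sequence_length=1314, k=5)

print(f"sequence length : {len(gold.source_sequence)} nt")
print(f"k-mer model     : k={model.k}, {len(model.levels)} levels")
print(f"gold events     : {len(gold)}  (= sequence length - k + 1)")
print(f"level range     : {gold.events.min():.1f} - {gold.events.max():.1f} pA-scale")

# Comparisons downstream happen on z-normalized signals.
z = sq.z_normalize(gold.squiggle)
print(f"z-normalized    : mean {np.mean(z.events):+.2e}, std {np.std(z.events):.6f}")
print("The z-normalized gold is the reference every mock or real squiggle is aligned to.")
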