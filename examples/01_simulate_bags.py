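"""Generate a synthetic set of molecules (bags of conformer fingerprints).

A bag is positive iff at least one conformer is a planted *witness* carrying
a designated 12-bit pharmacophore pattern — the multiple-instance axiom by
construction.
"""

from milespharm import SynthSpec, generate

dataset, truth = generate(SynthSpec(seed=7))

n_pos = sum(1 for b in dataset.bags if b.label == 1)
n_witness = sum(len(v) for v in truth.witness_flags.values())
print(f"bags: {dataset.n_bags} ({n_pos} active / {dataset.n_bags - n_pos} inactive)")
print(f"conformers: {dataset.n_conformers}, bit universe: {dataset.bit_universe}")
print(f"witness conformers planted: {n_witness}")
print(f"witness pattern bits: {sorted(truth.witness_sets[0])}")
# Each active molecule hides >=1 witness among its conformers; the task is to
# classify molecules and point at the witness without conformer-level labels.
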