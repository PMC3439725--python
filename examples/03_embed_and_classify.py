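"""Minimum-distance embedding plus 1-norm SVM classification.

Molecules are embedded as vectors of min dissimilarities to every training
conformer; the L1-penalized linear program picks a sparse set of prototype
conformers and classifies bags with them alone.
"""

import numpy as np

from milespharm import (
    FeatureRegistry,
    SynthSpec,
    build_embedding,
    fit_l1svm,
    generate,
    predict,
    prototypes,
    select_significant_bits,
)

dataset, truth = generate(SynthSpec(seed=7))
selected, _, _ = select_significant_bits(dataset, n_perm=500, seed=11)

registry = FeatureRegistry.from_bags(selected.bags)
emb = build_embedding(selected.bags, registry, "manhattan")
print(f"embedding: {emb.values.shape[0]} bags x {emb.values.shape[1]} conformer features")

model = fit_l1svm(emb.values, selected.labels().astype(float), lam=0.25,
                  registry=registry, metric="manhattan")
acc = float((predict(model, selected.bags) == selected.labels()).mean())
print(f"training accuracy: {acc:.3f}")
print(f"prototype conformers (|Γ|): {model.gamma().size} of {len(registry)}")
for r, w, sign in prototypes(model):
    bag_id, cid = registry.pairs[r]
    is_wit = cid in truth.witness_flags.get(bag_id, ())
    print(f"  ω={w:+.3f}  {bag_id}/{cid}  ({'witness' if is_wit else 'background'})")
# Negative weights mean 'being close to this conformer votes active': the
# prototypes the LP keeps are witness conformers.
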