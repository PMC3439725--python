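# Methods

## Model

A molecule **M**ᵢ is a bag of conformers **C**ᵢⱼ, j = 1…nᵢ, each encoded as a
sparse binary pharmacophore fingerprint over a shared universe of m bits.
Labels are ±1 at the bag level only. The working assumption is the
multiple-instance axiom: a bag is positive iff at least one instance is
"responsible". The pipeline converts this into standard supervised learning
by embedding every bag as its vector of minimum dissimilarities to all n
training conformers (the instance-based feature space), then fits a sparse
linear classifier whose surviving features — prototype conformers — drive
both prediction and the attribution of activity to individual conformers.

## Pharmacophore fingerprints

Keys are 4-point: four typed features (D, A, H, N, P, R) plus the six
pairwise distances, each discretized into 2-Å bins over 2.0–20.0 Å
(half-open `[2,4) … [18,20]`, the last bin closed; bin index
`floor((d−2)/2)`). A distance *strictly* within 1.0 Å of an interior bin
edge also matches the adjacent bin (a distance exactly 1.0 Å from the edge
does not), so one quadruplet expands into up to 2⁶ keys; this makes a
regular tetrahedron with 3.0-Å edges produce exactly one key and one with
3.5-Å edges produce 64. Quadruplets with any distance outside 2–20 Å
produce nothing; conformers with <4 feature points get empty fingerprints
(three points cannot orient a structure in 3D).

Canonical form: the lexicographic minimum over all 24 orderings of the four
points of the tuple (types, six ordered bin indices). This is a total,
permutation-invariant rule with no unspecified ties. Keys are distance-only
and therefore achiral; an off-by-default option appends the sign of the
tetrahedron volume to the key for users who want mirror images split.
Bit indices come from a global key table frozen in sorted-key order, so the
key→bit mapping is a pure function of the observed key set.

Occurrence filtering is molecule-level: a bit counts once per molecule if
any conformer carries it, and is retained iff its molecule fraction is
≥ `min_fraction` (default 0.05; the boundary value is kept, matching a
"present in less than 5%" removal rule).

## Significance analysis

Bit selection follows the significance-analysis-of-microarrays recipe on
molecule-level occurrence. Per bit, score = (mean occurrence in positives −
mean in negatives) / (pooled SE + s₀). Because occurrence is binary, class
variances follow from class means, which lets the 500 label permutations be
computed as two matrix products. Choices the underlying references leave
open, fixed here:

- **s₀** — the 5th percentile of the per-bit pooled SEs (a simplified
  fudge factor; configurable). If that percentile is 0 (many constant
  bits), a small positive floor tied to the SE scale is used so scores stay
  finite.
- **Two-sided selection** on |score|, so bits enriched in the negative
  class are also eligible; they carry real class information.
- **Reference scores**: mean over permutations of the rank-ordered permuted
  |scores|; the significance threshold is the 90th percentile of the pooled
  permuted scores.
- **Falsely-significant count at Δ**: median over permutations of the
  number of permuted scores ≥ the smallest truly-significant true score
  (zero when nothing is called).
- **Δ\***: smallest value on a 100-point grid from 0 to the largest
  true-minus-reference gap at which the false count reaches zero; if it
  never does, the largest grid value is used and a warning raised.

The same s₀ is reused for permuted scores (standard SAM practice).

## Embedding

Four binary dissimilarities in the a/b/c/d match-count convention, all with
range [0,1]: Soergel (b+c)/(a+b+c), Dice (b+c)/(2a+b+c), Manhattan
(b+c)/(a+b+c+d), Rogers–Tanimoto 2(b+c)/(a+d+2(b+c)). The 0/0 case (two
all-zero fingerprints under Soergel/Dice) is defined as 0 — identical
objects. Soergel and Dice are monotone transforms of each other at fixed
counts, so they share argmins. Bag-to-instance distance is the minimum over
the bag's conformers, with ties broken toward the lowest conformer index —
downstream significant-conformer sets depend on this determinism. The l × n
matrix is materialized densely (desk-scale problems); intersections come
from one sparse matrix product.

## 1-norm SVM

The exact LP: minimize λΣᵣ(uᵣ+vᵣ) + Σᵢξᵢ subject to
yᵢ((u−v)ᵀxᵢ + b) ≥ 1 − ξᵢ with u, v, ξ ≥ 0 and b free (split into two
nonnegative parts), solved with HiGHS; non-optimal solver status is an
error. ω\* = u − v; weights with |ω\*ᵣ| ≤ 10⁻⁸ are zeroed and Γ is the
set of surviving columns, both signs included (a signed weight still marks
an informative prototype). Dissimilarities enter unscaled — they are
already in [0,1]. Prediction computes distances only to Γ, which equals the
full-weight decision exactly.

λ is tuned on a base-2 grid 2⁻⁸…2⁵ by five replications of stratified
5-fold CV on bags. Within each fold the registry is rebuilt from the
fold-training bags only, so held-out molecules contribute no feature
columns. Per λ, fold accuracies are averaged and the median over
replications is maximized; **ties go to the largest λ** (the sparser
model). On strongly separable data this rule deliberately returns very
sparse models (|Γ| of 1–2 on the default synthetic fixture) — see
Limitations.

## Conformer identification

For a bag, each prototype r ∈ Γ is won by the bag conformer closest to it
(lowest index on ties); the distinct winners form Σ, and the won prototypes
Γⱼ\* partition Γ, so the contributions
f(**C**ᵢⱼ\*) = Σ_{r∈Γⱼ\*} ω\*ᵣ D(**C**ᵢⱼ\*, **C**^r) sum exactly to the
decision value minus the bias. The top contributor in Σ is reported as the
putative bioactive conformer.

Ranking convention: conformers outside Σ are irrelevant to the
classification — contribution exactly 0 and rank "N.A.". Σ members are
ranked by f descending **among Σ**, ties sharing the worst rank. When all
contributions are positive (the regime on real data where many prototypes
of both signs exist) this coincides with ranking among all conformers; on
data where informative prototypes carry negative weights (closeness to an
active-like conformer votes active, so every Σ member has f ≤ 0), ranking
against the zeros of non-participating conformers would be meaningless, and
the within-Σ rule keeps "unique Σ member ⇒ rank 1" true in both regimes.

The seeded-conformer protocol inserts externally supplied conformers
(flagged `seeded`) into bags before the pipeline runs and asks where they
land in the ranking — the synthetic stand-in for seeding co-crystallized
ligand conformers.

## Train/test split

A small Kohonen map clusters molecules by bag-union fingerprints, then each
occupied neuron is sampled into the training set with label stratification
(round-half-up per neuron×label cell, a global adjustment hitting the exact
3:1 target). SOM schedule (the original tool's is proprietary, so this is
the package's own, documented stand-in): rectangular lattice, online
updates, Gaussian neighborhood with radius decaying linearly from
max(w,h)/2 to 1, learning rate 0.5 → 0.01 linearly, weights initialized
uniform [0,1] from the seed.

## Baselines

Classical QSAR view: one union fingerprint per molecule (bitwise OR over
conformers), same filtering and significance selection. Decision tree (Gini,
minimum 3 molecules per leaf) and random forest (library defaults) are
delegated to scikit-learn; the 1-norm SVM baseline reuses this package's LP
with its own λ tuning on the fixed union-feature matrix. MCC follows the
usual formula with the convention that a zero factor in the denominator
yields 0.

## Synthetic data

The generator emulates the MIL axiom at the fingerprint level (no 3D
geometry): background bits fire at rate `p_bg`; witness conformers
additionally switch on the bits of a designated disjoint witness pattern at
rate `p_w`; every bit is then flipped with probability ε. Witness bits ride
on top of the background, so inactive molecules can carry scattered witness
bits by chance — this is what makes the minimum-distance embedding
non-trivial. Defaults (the canonical fixture): 80 bags, balance 0.5,
3–10 conformers per bag, 400 bits, one 12-bit witness pattern, p_bg = 0.05,
p_w = 0.95, ε = 0.01, seed 7. The fraction of an active bag's conformers
that are witnesses defaults to 0.25 (at least one forced) — roughly "a
quarter of sampled shapes could bind", a middle ground between a single
needle in the haystack and a trivially redundant signal. One seeded RNG
stream ordered bags → conformers → bits makes generation byte-reproducible.

What this emulates and what it does not: it reproduces the bag/instance
label structure, sparse correlated fingerprints, and label-independent
noise; it does not reproduce conformer–conformer geometric correlation
within a molecule, feature-count heterogeneity across chemotypes, or
assay-label noise. Passing tests therefore demonstrate the machinery —
embedding, LP sparsity, attribution identities, calibration of the
permutation analysis — not performance on any real compound series.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale (≤ 80 molecules, ≤ 520
conformers, 400 bits, 500 permutations, full 14-point λ grid with 5×5-fold
CV), chosen so the entire suite completes in a few minutes on one CPU while
still exercising every code path end to end. LP optimality is asserted to
1e-8 against an independently formulated LP; the contribution-conservation
identity holds to 1e-10; distance computations are exact integer-count
arithmetic.

## Known limitations

- Chemical feature perception is out of scope: feature points (or
  ready-made fingerprints) are inputs.
- Distance-only 4-point keys are achiral; the signed-volume option is a
  pragmatic extension, not a validated chirality encoding.
- On strongly separable data the largest-λ tie rule collapses the model to
  one or two prototype conformers. Classification and witness attribution
  are unaffected, but the seeded-conformer ranking protocol loses power:
  with so few prototypes, an inserted conformer that is statistically
  exchangeable with the bag's own witnesses rarely wins a prototype, so its
  rank is usually "N.A.". A multi-prototype regime (hundreds of embedded
  features, as on real compound sets) is needed for that protocol to be
  informative.
- The SOM training schedule is a documented stand-in, not a reproduction of
  any proprietary implementation.
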