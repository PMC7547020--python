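# Methods

## Model

An image is reduced to a fixed-length feature vector by a frozen pretrained
network ("image signature"); the trainable model is a single
fully-connected layer over that vector:

```
z = w x + b          w: (dim, 2), b: (2,)
ŷ = g(z)             g ∈ {softmax, softplus, softsign, relu, leaky_relu,
                          log_softmax, identity}
```

Class encoding: column 0 = NOTACP, column 1 = ACP (positive). The loss is
the two-class Bernoulli cross-entropy of the predicted ACP probability,
optionally plus `l1 · Σ|w|` and/or `l2 · Σw²`. For non-normalizing
activations the activated scores are passed through a softmax before the
loss so the cross-entropy contract is uniform across genomes; gradients
carry the extra elementwise `g'(z)` factor, verified against central
differences to 1e-5 for every activation × regularization combination.

Dropout is inverted (train-time scaling by `1/keep_prob`, evaluation is the
identity). Parameters start at zero; with the softmax head the problem is
convex, so zero init plus a seeded shuffle makes every run exactly
reproducible. Features are standardized to zero mean / unit variance using
training statistics, and the affine transform is folded back into `(w, b)`
after training so the stored parameters apply to raw embeddings — this
keeps whole-batch gradient descent well-conditioned when embeddings share a
large mean component, without changing the model class.

The optimizer catalogue is implemented by hand (no autodiff framework):
SGD; Momentum (0.9); Adam (0.9/0.999); Adagrad (initial accumulator 0.1);
Adadelta (ρ = 0.95); RMSProp (decay 0.9); FTRL (learning-rate power −1/2);
and proximal variants of Adagrad/Adadelta where an L1 soft-threshold and/or
L2 shrinkage (strength 0.001, scaled by the learning rate) follows the base
step. With the four proximal regularization modes counted as separate
variants the optimizer axis has 15 entries.

## Search space and genetic algorithm

The phase-1 space is the product of ten categorical axes:

| axis | variants |
| --- | ---: |
| network | 12 |
| learning rate | 7 |
| batch size | 3 |
| epochs | 5 |
| optimizer | 15 |
| activation | 7 |
| dropout keep | 4 |
| regularization | 4 |
| training dataset | 3 |
| test dataset | 3 |

Total: 12·7·3·5·15·7·4·4·3·3 = **19,051,200** genomes. A 10-generation ×
100-individual run evaluates at most 1,000 of them — 0.005% of the space.

Each generation is ranked by fitness (test AUC; ties broken by accuracy,
then genome hash, so the ranking is deterministic). The top 40% survive;
each individual below the cut is kept anyway with probability 10%
("negative rejection", preserving diversity); children are bred by copying
each axis from one of two distinct survivors with equal probability, and
with probability 20% one uniformly chosen axis is resampled. Elites carry
their cached fitness, so best fitness is non-decreasing.

Evaluation purity: fitness is a pure function of
`(genome, eval_seed)` where
`eval_seed = (master_seed · 1,000,003 + stable_hash(genome)) mod 2³¹` and
`stable_hash` is a SHA-256 digest of the sorted axis choices. Because the
seed never depends on execution order, threaded and serial searches produce
identical generation histories (asserted in the tests with an
eval-seed-sensitive fitness).

## Data handling

Augmentation stages (train-time probabilities): grid distortion (p = .75,
4×4 lattice, magnitude 8, bilinear displacement field), right-angle
rotation (p = .75), area zoom (p = .5, area fraction .8), horizontal flip
(p = .5). Test-set replication uses the same stages with all probabilities
1.0. Class-balanced oversampling draws parents uniformly per class per
modality until each cell reaches the target (e.g. 1000), recording
`parent_image_id` for provenance; originals are retained.

Cross-validation scenarios (5-fold, stratified by class via seeded
round-robin dealing):

1. originals + augmented pooled, folds split at the *image* level —
   deliberately leaky: descendants of a validation image can train the
   fold's model;
2. folds split at the *patient* level over originals; augmented images
   join only training folds, and only as descendants of training-fold
   originals;
3. patient-level folds over originals only.

A leakage scanner walks every fold and reports train/validation pairs that
share an image origin; it is empty for scenarios 2–3 by construction and
non-empty for scenario 1 whenever augmented data exists.

## Phantom design

The clinical images are private, so experiments run on structurally
matched phantoms: 299×299 uint8 images, two modalities with distinct base
textures (CT: dark field with a bright rim; MRI: brighter field with a
smooth low-frequency modulation), a central elliptical "sellar" ROI, and
per-patient latent structure (lesion geometry drawn once per patient,
shared across that patient's images with small jitter) so patient-level
and image-level splitting genuinely differ.

- ACP texture: bright speckled blobs plus a ring inside the ROI
  (calcification / cyst-rim analogue).
- NOTACP texture: one smooth Gaussian disc (solid homogeneous mass).
- Both scale with `signal_amplitude`; at amplitude 0 the classes are
  identically distributed.
- `confound_amplitude` adds a corner gradient whose *sign* tracks the
  class — class signal deliberately placed outside the ROI.

Default cohort shape: 23 ACP + 30 NOTACP training patients × 3 images ×
2 modalities = 318 training images; 16 + 17 test patients × 1 image ×
2 modalities = 66 test images. The NOTACP differential composition
(13 diagnoses) sums to 47 patients = 30 train + 17 test.

The offline mock extractor pools per-cell mean/std on an 8×8 grid and
projects the 128 statistics through a fixed seed-derived linear map. The
leading output columns are averages over orbits of the grid cells under the
right-angle rotation/flip group — approximately invariant to the
augmentation pipeline's rotations and flips, the way deep embeddings are —
while the remaining columns are random projections retaining full spatial
specificity. Grid pooling makes the features local, which is what lets ROI
masking visibly remove information.

## What the experiments show — and don't

Shown on phantoms (test suite assertions):

- high intra-ROI signal → hold-out and scenario-2 CV AUC ≥ 0.95;
- zero signal → mean AUC across 20 seeds inside the 0.35–0.65 chance band;
- masking the ROI collapses the AUC when the signal is intra-ROI only, and
  leaves it ≥ 0.8 when an extra-ROI confound exists;
- image-level pooled CV (scenario 1) reads higher than patient-level CV
  (scenario 2) on identical moderate-signal data (paired comparison,
  median over 10 seeds);
- the GA finds a hidden optimum in a 4096-genome space in ≥ 90% of 50
  seeded runs with a 10×20 budget.

Not shown: any clinical performance claim. The headline accuracies of the
motivating study are functions of private patient images and of real
pretrained embeddings; neither ships here, and no synthetic result
transfers to them.

## Numerical choices

- ROC: scores sorted descending (stable), tied scores grouped into a
  single threshold step, `(0, 0)` sentinel prepended, trapezoidal
  integration — equal to the tie-corrected Mann–Whitney statistic
  (asserted to 1e-12 against a brute-force pairwise oracle).
- Logits clipped to ±1e6 before activation to avoid overflow in pathological
  configurations; softmax computed with the max-subtraction trick.
- Probability clipping floor 1e-12 in the cross-entropy.
- Batch sizes `{5, 20, 120}` and an `identity` activation are
  implementation choices for axes whose exact published variants are
  ambiguous; they preserve the axis multiplicities (3 and 7).
- Per-genome evaluation seeds < 2³¹ so they are valid for every RNG
  consumer.

## Limitations

- The mock extractor is a linear map over pooled statistics: it validates
  plumbing and locality properties, not representation learning.
- Phantoms are geometric textures, not anatomy; their difficulty is tuned
  by amplitude/noise, not by realistic inter-patient variability.
- The CT–MRI concatenation pairs images within patient by sorted id (with
  index truncation for unequal synthetic counts), a simplification of how
  multimodal fusion would be done with registered clinical series.
- FTRL and the proximal wrappers implement one canonical form each; other
  published variants differ in accumulator details.
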