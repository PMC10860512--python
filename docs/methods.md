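# Methods

## Problem and study design

`gtvseg` implements, end to end, a two-hospital transfer-learning study for
automatic lung gross-tumour-volume (GTV) segmentation on CT. The design has
four cohorts:

* **source train** — a large "generic" cohort from the source domain, used to
  pretrain the segmentation network (Model 1);
* **source interobserver** — source-domain subjects in which K = 5 observers
  independently delineate the same tumour; kept as a constant test set;
* **target retrain** — a small cohort from a second, shifted acquisition
  domain, used to fine-tune Model 1 into Model 2;
* **target test** — held-out subjects from the shifted domain, never used in
  any training.

Both models are evaluated on both test sets with volume-level Dice (DSC),
precision and recall; observer agreement is measured pairwise (10 pairs for
K = 5) and through nested consensus regions (voxels marked by at least k of
K observers); methods are compared with one-way ANOVA and Tukey's HSD.

Because no patient data ship with the package, all cohorts come from a
synthetic phantom generator that reproduces the *mechanisms* the study needs
— an acquisition-domain shift and multi-observer delineation variability —
without attempting anatomical realism.

## Phantom model

Each subject is an axial stack (8–12 slices at 64 × 64 px by default) with

* a soft-tissue body disc (default 40 HU) on an air background (−1000 HU),
* two elliptical lung fields (−800 HU), and
* one tumour: an ellipsoid with radius drawn uniformly from a configured
  physical range, whose boundary is perturbed by a smooth Gaussian random
  field (correlation length 4 mm) scaled by an `irregularity` knob in [0, 1];
  at irregularity 0 the mask is exactly the discretized ellipsoid, which is
  what the geometry tests exploit.

A `DomainSpec` adds per-domain Gaussian noise (`noise_sd_hu`), a global
calibration shift (`intensity_offset_hu`), slice thickness, the tumour size
range, and patient orientation. The default source domain is 3 mm slices,
noise 10 HU, no offset, tumour HU in (10, 80) and radii 3.5–6.5 mm. The
default target domain is 5 mm slices, noise 30 HU, offset +100 HU, tumour HU
in (−40, 30) and radii 5–8 mm, stored feet-first (exercising orientation
canonicalization). The offset magnitude is on the scale of a
contrast-enhancement / calibration difference between scanners; together
with the shifted tumour band it places target tumour intensities outside the
band the source model was trained on, which is what makes the domain shift
*genuine* rather than cosmetic — with a weaker offset the pretrained model
often generalizes across domains and there is nothing for transfer learning
to recover (we observed exactly this in pilot runs, and the literature's
motivation presumes the shift matters). Larger tumours in the target domain
echo the later-stage case mix of the local clinic.

Observer simulation operates on the signed Euclidean distance d(x) to the
truth boundary (negative inside, in mm): observer i's mask is
{x : d(x) ≤ b_i + f_i(x)} with a constant per-observer bias b_i and a smooth
zero-mean field f_i with standard deviation `boundary_sd_mm`. Working in
millimetres makes observer behaviour invariant to voxel spacing. Defaults
(sd 1.5 mm, biases ±0.7, ±0.35, 0 mm) were calibrated so pairwise observer
DSC on default phantoms has median in the 0.7–0.9 band reported for
independent experts; this is a property of the simulator's configuration,
not a claim about any particular clinicians. Masks are reduced to their
largest connected component, and a configuration that empties a mask raises
an error instead of silently producing a degenerate observer.

What the phantoms deliberately do **not** model: anatomy (vessels, airways,
mediastinum), texture, partial-volume effects, reconstruction kernels, or
PET. Consequently the absolute scores the pipeline produces are far higher
than on clinical data — the tumour is the only bright object inside the
lung, so a converged network can segment it almost perfectly. Passing tests
therefore demonstrate that the *machinery* (training, transfer, evaluation,
statistics) behaves correctly and that the *directional* findings
(performance drop under domain shift, recovery after fine-tuning, stability
on the source test set, recall declining with weaker observer consensus)
are reproduced; they say nothing about clinical-grade accuracy.

## Preprocessing

CT volumes are windowed to [−150, +250] HU and mapped linearly onto [0, 1].
The divisor is the fixed window width, not a per-image min/max: with a fixed
window both readings of "min–max normalization" coincide for images that
fill the window, and the fixed map keeps a given HU value at the same
normalized intensity in every image and domain, which cross-domain
comparison requires. No spatial resampling or interpolation is performed
anywhere; volumes are decomposed into 2D slices for training and restacked
for evaluation with 0-based slice indices. Feet-first stacks are flipped to
a canonical head-first order on read (the NIfTI affine's slice-direction
sign carries the orientation on disk).

## Network

A 2D attention U-Net implemented in numpy (forward, backward and the Adam
optimizer are part of this package; there is no deep-learning framework
dependency). A block is batch-norm → conv 3×3 (stride 1, pad 1) → leaky
ReLU(0.1) → conv 3×3 → leaky ReLU(0.1); batch normalization prefixes every
block — encoder, bottleneck and decoder alike. Depth d gives d encoder
blocks (each followed by 2×2 max-pooling, channels doubling from
`base_channels`), one bottleneck and d decoder blocks: 9 blocks at the
standard depth 4. Decoder levels upsample by nearest-neighbour 2× followed
by convolution (avoiding transposed-convolution artefacts), merge the
attention-gated skip by concatenation, and the head is a single 1×1
convolution with a sigmoid.

The additive attention gate computes α = σ(ψ(ReLU(W_x·skip + up(W_g·g)))),
with the coarser decoder-side feature as the gating signal g and
inter-channel width half the skip channels. This follows the standard
additive-gate formulation; gates expose a `force_alpha` hook so tests can
pin α = 1 and verify the network collapses to a plain U-Net.

Numerical choices: float32 arithmetic throughout; He-uniform weight
initialization from a recorded seed; batch-norm eps 1e-5 and running-moment
momentum 0.1, with running statistics frozen at inference so prediction is
deterministic; max-pooling ties route to the first maximal position.

## Training and transfer learning

The loss is soft Dice, computed per image and averaged over the batch:
L = 1 − (2Σpt + s)/(Σp + Σt + s) with smoothing s = 1 by default, which
keeps the loss finite and informative on tumour-free slices. Optimization is
Adam over shuffled slice batches (batch size 6). Validation splits are at
the subject level (never slice level), |val| = round(f·n) with minimum 1.
The retained checkpoint is the lowest-validation-loss epoch, not the last.

Fine-tuning continues training of *all* weights from the pretrained
checkpoint on the target retraining cohort. The guard against catastrophic
forgetting has three standard components: early stopping when the
new-domain validation loss stops improving (patience 10 epochs at desk
scale) plus the best-checkpoint rule; a fine-tuning learning rate five-fold
below the pretraining rate; and frozen batch-norm statistics
(`freeze_bn_stats`) — during fine-tuning every batch-norm layer normalizes
with the running moments inherited from pretraining instead of batch
statistics. The last matters most under a strong intensity shift: running
moments otherwise converge to the new domain within a few dozen batches,
which alone degrades source-domain predictions regardless of how small the
weight updates are (we measured interobserver median-DSC drops up to 0.11
without the freeze). When a source-domain validation set is supplied,
source validation Dice is recorded per epoch so forgetting is directly
measurable in the history.

Two presets ship. `paper_faithful` keeps the full-scale protocol (512 px
inputs, learning rate 1e-6, 300-epoch pretraining, ≤150-epoch fine-tuning)
for users with real data and hardware to match; it is not exercised by the
test suite. `desk_scale` is the profile the shipped study uses and was sized
to run end to end in minutes on one CPU: 64 px slices, depth 3, 8 base
channels, learning rate 1e-3 (2e-4 for fine-tuning), 30 pretraining and ≤25
fine-tuning epochs, cohorts of 40/8/12/16 subjects, and tumour-free training
slices capped at a 1:1 ratio to tumour slices (`max_empty_ratio`) so the
network still learns to emit empty masks without empty anatomy dominating
the epoch. Volume prediction thresholds per-pixel probabilities at 0.5
(configurable) and applies no inter-slice post-processing.

The training surface is also exposed as a scikit-learn style estimator
(`AttentionUNetSegmenter`, with fit/predict/predict_proba/score,
`get_params`/`set_params` and `warm_start` for continued training), so the
model composes with sklearn tooling; the cohort-level functions
(`train`, `fine_tune`, `predict_volume`) are thin wrappers over the same
loop.

## Evaluation conventions

Metrics are computed from voxel confusion counts over the whole volume
(per-patient reporting). Degenerate cases: both masks empty → all three
metrics 1.0, flagged; empty prediction against a non-empty reference →
DSC 0, recall 0, precision undefined (NaN, excluded from aggregation);
non-empty prediction against an empty reference → DSC 0, precision 0,
recall undefined. DSC equals the harmonic mean of precision and recall
wherever both are defined, and the suite asserts this identity on every
random record.

Consensus regions use cumulative agreement ("at least k of K"), so regions
are nested by construction. Consensus recall at level k is
|pred ∩ region(k)| / |region(k)|, reported from the unanimous core (k = K)
down to the union (k = 1).

For ANOVA the grouping unit is one score per subject for model arms (the
median over the K observer references where several exist) and one score
per subject-pair for the manual arm (a flag switches to per-subject
medians). ANOVA uses the classical between/within mean-square ratio and
Tukey HSD the studentized-range adjustment (scipy implementations behind
this package's interface; the test suite checks both against an independent
textbook sums-of-squares implementation and statsmodels). Summaries use the
linear-interpolation quantile rule; α = 0.05.

## Reproducibility

Every stochastic component (phantom geometry, noise, observer fields,
weight initialization, data shuffling, cohort splits) draws from a stream
derived from one master seed via `numpy.random.SeedSequence`, with disjoint
sub-streams per cohort and stage. Two executions of the same manifest on the
same machine produce byte-identical report JSON, which the test suite
asserts. `scripts/acceptance.py --seed S --out f.json` reruns the whole
study for master seed S and writes the headline quantities it computed.

## Known limitations

* Phantom simplicity saturates absolute scores (see above); only
  directions and invariances transfer to real data.
* The attention-gate channel arithmetic follows the published additive-gate
  formulation; implementations differ in minor details (gate width, where
  the gate is resampled) and no claim is made of matching any specific
  diagram.
* Training is single-threaded CPU numpy; the `paper_faithful` preset is
  provided for completeness but is impractical without substituting a GPU
  implementation.
* The statistical layer assumes independent scores within groups; scores
  sharing a subject (model-vs-each-observer) violate this mildly, which is
  why the per-subject-median pooling is the default for model arms.
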