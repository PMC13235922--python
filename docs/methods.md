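# Methods

## Problem setting

A QCL-IR chemical image is an `H x W x B` absorbance cube: every spatial
pixel carries a full mid-infrared spectrum over the fingerprint region
(default axis 952–1800 cm⁻¹, 213 evenly spaced channels, 4 cm⁻¹ spacing).
Labels (tumour model, treatment response) exist per image, not per pixel.
The package casts each image as a bag of `K = H·W` instance spectra and
trains an attention-pooling MIL classifier so that (i) bags are classified
from image-level labels alone and (ii) the attention weights localise the
pixels that carried the decision.

## Preprocessing

Applied in a fixed order, per spectrum: rubber-band baseline correction,
tissue masking, zero-filling, vector normalisation.

* **Rubber-band baseline.** The baseline is the lower convex hull of the
  points (νᵢ, Aᵢ), linearly interpolated between hull vertices, computed
  with an Andrew monotone-chain scan (O(B), deterministic; collinear points
  are kept on the hull, which leaves the interpolated envelope unchanged).
  The corrected spectrum is non-negative and exactly zero at hull contacts,
  and the operation is invariant to adding any affine function of
  wavenumber — the defining property of scattering-drift removal. Round-off
  negatives (~1e-16) are clipped to zero.
* **Tissue mask.** A pixel is tissue iff its baseline-corrected absorbance
  at the channel nearest 1654 cm⁻¹ (Amide I) is ≥ 0.1. The threshold is
  applied after baseline correction, matching the listed pipeline order;
  masking depends on that single channel only.
* **Zero-filling.** Background spectra are replaced by exact zero vectors so
  the spatial grid (and hence the attention map geometry) is preserved.
* **Vector normalisation.** Remaining tissue spectra are scaled to unit
  Euclidean norm (thickness correction); the zero vector maps to itself.
* **AUC morphology image.** Per-pixel trapezoidal integral of absorbance
  over the full axis; used as the greyscale background under attention
  overlays.

EMSC/Mie correction and derivative smoothing are deliberately out of scope.

## Model

Instance encoder: an input linear layer `B → N_HLN`, then `N_B ∈ {1,2,3}`
blocks of linear → batch-norm → ReLU. Block b has width `N_HLN·2^(b−1)`
(expanding) or `⌊N_HLN/2^(b−1)⌋` (shrinking); widths must stay ≥ 1. An
optional residual connection adds the block input to the block output, with
a learned bias-free linear projection on the skip path when the widths
differ. Attention pooling (`V ∈ R^{L×M}`, `w ∈ R^L`, softmax with
max-subtraction) produces the bag embedding `z`, and a single linear layer
maps `z` to class logits. Defaults: the two-block shrinking network
(`213 → 64 → 64 → 32`, no residual) with attention dimension `L = 128`
(the attention hidden width is not dictated by the task; 128 follows the
common MIL-attention convention) — the configuration that wins the
architecture grid search under the peak-selection rule.

The network is implemented directly on NumPy arrays with hand-written
reverse-mode gradients (verified against central finite differences in the
test suite) and a standard Adam optimiser (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).

### Batch normalisation in a bag-batch regime

Each optimisation step processes one bag, so the "batch" a batch-norm layer
sees is the bag's K instances. Two normalisation modes are provided:

* `bn_train_mode="batch"` (classic): normalise with the bag's own
  statistics. In this regime the per-bag statistics themselves carry
  class information (bags differ in their instance distributions), and the
  optimiser can drive the training-mode loss to ~0 by exploiting those
  constants while the evaluation-mode model — which must use running
  statistics — stays near chance. We observed exactly this failure mode on
  the phantom: step losses of 0.65 → 0.03 with evaluation macro-F1 stuck at
  0.33–0.56, and re-estimating the running statistics after training does
  not recover it, because the learned solution lives in the per-bag
  geometry.
* `bn_train_mode="running"` (default): normalise with the running
  statistics during optimisation too, reading them *before* the EMA update
  (momentum 0.1, unbiased variance) so the normalisation constants are
  genuinely constant with respect to the current bag and backpropagation is
  exact. Training and evaluation then share one geometry, the label cannot
  leak through normalisation, and training converges for every seed we
  probed instead of intermittently.

Evaluation mode always uses running statistics, which makes the forward map
exactly row-wise: a K = 1 bag, instance permutations and identical-instance
bags behave as the pooling algebra dictates.

## Training protocol

Adam on bag-level cross-entropy, one bag per step, bags visited in
seed-shuffled order per epoch; no early stopping, schedules or weight decay.
After each epoch both splits are evaluated (loss, macro-F1, accuracy;
macro-F1 is the unweighted per-class mean, with never-predicted classes
contributing 0 — this is the convention under which a constant binary
predictor on balanced data scores exactly 1/3 at accuracy 1/2). The returned
model is the checkpoint with the strictly highest validation macro-F1,
earliest epoch on ties (deterministic, and favouring less-overfit
parameters). Splits are made at the animal level: whole animals are
assigned to one subset, ordered by interleaving treatment groups so both
subsets see every treatment whenever the grouping permits, greedily filling
the per-class image target. A class with fewer than two animals cannot be
split and raises.

Hyperparameter search is two-stage: all 36 architecture combinations
(depth × first-hidden × expansion × residual) at learning rate 1e-3, then a
learning-rate sweep {1e-1, 1e-3, 1e-5} on the winner; every combination is
replicated over ≥ 3 seeds. Both selection rules are implemented — `mean`
(seed-averaged validation F1) and `peak` (single best run, the default) —
with ties broken toward fewer blocks, fewer hidden nodes, no residual.

## Explainability

* **Attention.** Per-bag weights are min-max normalised to [0, 1] (a
  constant field maps to all zeros — flat attention carries no saliency),
  scattered back to the `H × W` grid through the bag's index map, and
  overlaid on the AUC image. The top `⌈0.05·K⌉` instances by raw weight
  (ceil; ties at the cut keep the smaller index) form the salient-spectra
  subset for downstream analysis.
* **Expected gradients.** Attribution of the instance-level class score
  (classifier ∘ encoder in evaluation mode): for instance x, background b
  and path position α ~ U(0,1), attribution = E[(x−b) ⊙ ∇f_c(b + α(x−b))] —
  sampled integrated gradients with a background distribution. Background:
  512 instances subsampled from the validation bags; 64 path samples by
  default; at most 2,000 (non-zero) instances explained per bag for
  runtime, with a full-bag mode available. Summaries per class: mean
  |attribution| per wavenumber (importance ranking) and signed mean
  (direction of effect). For an affine score the estimator is exact, which
  the tests exploit (closed form and completeness checks via the identity
  activation hook).

## Downstream analysis

Top-attended spectra are standard-scaled (per-channel mean 0, population
SD 1), embedded to 2D with UMAP over a parameter grid (defaults
n_neighbors ∈ {5,10,20,40,80}, min_dist ∈ {0.1,0.25,0.5},
metric ∈ {euclidean, cosine, manhattan}; step sizes within the stated ranges
are a package choice), clustered with k-means (k = 7 by default, 10
restarts, fixed seeds throughout). Agreement with ground-truth labels is
scored by NMI = I(U,V)/√(H(U)·H(V)) computed from the contingency table
with natural logs — the geometric-mean normalisation; if either partition
has zero entropy the score is 1 for partitions identical up to relabelling
and 0 otherwise. The grid argmax resolves ties toward smaller n_neighbors,
then smaller min_dist, then metric name. k = 7 is kept configurable: the
cohort design yields eight model × treatment combinations, and the right
cluster count is a modelling choice, not a constant.

Band metrics per image: trapezoidal integrals of Amide I (1600–1700 cm⁻¹),
Amide II (1540–1560 cm⁻¹) and Amide III (1200–1350 cm⁻¹), plus
nearest-channel peak ratios (Amide I/II at ~1658/1544 cm⁻¹ and
protein-to-nucleic-acid/lipid ratios at common literature positions —
configurable, as exact windows vary between labs). Denominators below 1e-12
yield a flagged missing value, never infinity. Pearson correlations against
protein endpoints (Bim, Puma) use the sample (n−1) formulation with pairwise
deletion, computed independently per sensitivity group; cells with fewer
than 3 complete pairs are reported missing.

## The phantom generator

The synthetic cohort emulates the study design the method targets: 2 tumour
classes × 4 treatments (FOLFOX, ABT199, COMBO, VEHICLE) × 5 images per
cell = 40 images, one animal per image by default, images 64 × 64 × 213 at
desk scale (480 × 480 is supported but not the default; the tests and
examples state the sizes they use).

Per image: a contiguous tissue region (smoothed Gaussian random field
thresholded to exactly the target pixel count, default 50 % of pixels) on a
near-zero background; a salient sub-region (default 15 % of tissue pixels)
carrying the class-discriminative band — phosphate ~965 cm⁻¹ for class 0,
carbonyl ~1727 cm⁻¹ for class 1, amplitude 0.6 — plus treatment-specific
amide shifts; Gaussian absorption bands for the base tissue spectrum
(Amide I/II/III, nucleic-acid phosphate, CH deformation) with per-image
amplitude jitter (SD 15 %); paraffin bands at 1464/1373 cm⁻¹ everywhere
(sections are not dewaxed); a smooth per-pixel baseline drift
(offset/slope/curvature); and additive Gaussian noise (SD 0.01). Peaks are
truncated at ±5σ so planted effects are exactly zero outside their band
windows (the clipped tail is < 4e-6 of the amplitude). The class-effect
amplitude and salient fraction are chosen so the planted saliency is
unambiguous — strong enough that a correctly working pipeline classifies
held-out animals near-perfectly and concentrates attention on the planted
pixels by a wide margin, so test failures indicate implementation faults
rather than borderline task difficulty.

Protein endpoints are `r·z + √(1−r²)·ε` where z is the standardised planted
Amide-I integral of each image's salient mean spectrum and ε is standard
normal — so the cohort-level Pearson correlation approaches the configured
`protein_corr` (default 0.8) as the cohort grows.

All randomness derives from per-component seed streams (layout, jitter,
baseline, noise), so cubes regenerate bit-identically and two cubes with the
same seed but different class labels differ only in the class-effect
channels.

**What the phantom does not emulate:** Mie/resonant scattering line-shape
distortions, instrument noise structure (it uses i.i.d. Gaussian noise),
dewaxing chemistry, intra-tissue histological texture, and spatial
correlation of the noise. Passing tests therefore demonstrate that the
pipeline recovers planted signals of realistic shape and scale — not that
the method overcomes every artefact of real QCL-IR acquisition.

## Numerical choices and degenerate inputs

* Softmaxes (attention, cross-entropy) use max-subtraction.
* Batch-norm ε = 1e-5; Adam defaults; He initialisation for ReLU linears,
  Xavier for attention and classifier; all initialisation seeded.
* Zero spectra: vector normalisation and attention normalisation map
  degenerate (zero / constant) inputs to zeros rather than raising.
* Checkpoint, top-fraction, grid-search and selection ties all have
  documented deterministic tie-breaks (earliest epoch; smaller index;
  smaller n_neighbors/min_dist/metric name; smaller architecture).
* Problem sizes in tests: the end-to-end check uses the full 40-image
  64 × 64 × 213 design; unit-level fixtures use 16–24 px images, which keeps
  the whole suite in the low minutes on a laptop-class CPU.

## Known limitations

* Single-bag Adam training is sensitive to initialisation at very small
  cohort sizes (a handful of bags); with the default running-statistics
  batch norm this disappears at the 40-image scale, but tiny-cohort runs
  can still collapse to one class for some seeds.
* The expected-gradients implementation subsamples instances and paths;
  attributions are Monte-Carlo estimates, exact only for affine scores.
* UMAP determinism holds for a fixed `random_state` (which forces
  single-threaded layout); across library versions embeddings may differ.
* The MAT-file interface targets the HDF5-based (v7.3) layout only.
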