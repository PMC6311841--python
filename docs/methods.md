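# Methods

`sonodae` implements a two-stage analysis of breast-ultrasound lesion
ROIs: retrospective intensity-inhomogeneity (bias-field) correction,
followed by benign/malignant classification with a stacked denoising
autoencoder (SDAE) topped by a logistic-regression unit. A synthetic
phantom generator stands in for clinical data so that every stage can be
tested against known ground truth.

## Bias-field model and correction

The observed intensity at pixel *i* is modelled additively,

    O_i = mu_psi(i) + P(x_i, y_i) + n_i ,

where `psi(i) ∈ {F, B}` assigns the pixel to the hypoechoic lesion
foreground or the brighter background, `mu_F`/`mu_B` are the two region
means, `P` is a bivariate polynomial over coordinates normalised to
[-1, 1] per axis (`(2·idx − (len−1))/(len−1)`, 0-based), and `n_i` is
residual noise. `P` carries **no constant term**: a constant would be
absorbed by the region means and make the model unidentifiable, so the
coefficient vector covers the monomials `x^j y^k` with `1 ≤ j+k ≤ N`
(graded-lexicographic order, x-exponent descending within a degree). The
default degree is N=2; degrees 1–4 are accepted, higher degrees are
rejected because they chase speckle and condition the normal equations
badly.

Correction alternates two steps until the mean squared residual

    eps^2 = (1/Npix) · sum_i (O_i − mu_psi(i) − P_i)^2

stops improving (relative change < 1e-4, at most 10 outer passes):

1. **Fuzzy cell-based bipartition** of the current corrected estimate.
   The image is tiled into `cell_size × cell_size` cells (4 px default
   on 28×28 ROIs) and 2-cluster fuzzy c-means (fuzzifier m=2) runs on
   the per-cell mean intensities; pooling over cells regularises the
   cluster-centre estimates against speckle. The centres are
   deterministically initialised at the 5th and 95th percentiles of the
   cell means — a deliberately wide spread, because a small lesion
   contributes few cells and a narrower initialisation can drop both
   centres into the background mass, where FCM converges to a wrong
   split of the background. A second, pixel-level FCM pass seeded with
   the pooled centres then gives each pixel its own membership; this
   sharpens the foreground boundary below cell granularity, which
   matters because pixels mislabelled at cell granularity (~4% of a
   typical ROI) bias the subsequent surface fit appreciably. The
   lower-mean cluster is foreground (lesions are hypoechoic); hard
   labels use a 0.5 membership threshold.
2. **Joint least squares** on the *original* image: `mu_F`, `mu_B` and
   the polynomial coefficients are fitted simultaneously by linear least
   squares, the design matrix concatenating the two region-indicator
   columns with the monomial columns. Rank deficiency falls back to the
   minimum-norm solution with a logged warning.

The corrected image is `clip(O − P̂, 0, 1)`; since `P̂` has no constant
term the global mean is essentially preserved. If a re-bipartition would
*increase* eps², the previous iterate is kept and the loop stops, so the
eps² trace is non-increasing by construction. Degenerate inputs
(constant images, a bipartition with an empty region) return the input
unchanged with a zero surface and `converged=False` — correction never
crashes a pipeline run.

The additive model is used exactly as stated: no multiplicative or
log-domain variant, no filtering or histogram methods.

## SDAE classifier

Each layer is a tied-weight denoising autoencoder with sigmoid
activations: corrupt the input (masking noise, default level 0.3 —
each component zeroed independently; Gaussian corruption is available),
encode `z = σ(W x̃ + b)`, reconstruct `x' = σ(Wᵀ z + b')`, and descend
the mean batch squared reconstruction error `½‖x − x'‖²` against the
**clean** input by full-batch gradient descent. Corruption is resampled
every epoch. Layers are pretrained greedily: layer k+1 trains on the
clean (uncorrupted) encodings of layer k. After pretraining the decoder
biases are dropped and a single sigmoid output unit `S(V·z + c)` is
stacked on the top features; fine-tuning backpropagates through the
whole network, full batch, with cross-entropy loss by default (squared
error available). The head starts at zero, so an untuned model predicts
exactly 0.5; probability ≥ 0.5 maps to "malignant".

Defaults: hidden sizes (256, 64) for 784-dim inputs, learning rate 0.5
on the mean-form losses, 1000 pretraining epochs per layer and 10000
fine-tuning epochs. These were chosen so that plain full-batch descent
actually converges on ~150-sample training sets: mean-normalised
gradients with a few hundred epochs leave the network at its
initialisation, while the sum-form loss at the same rate oscillates.
Initial weights are Uniform(−r, r) with r = √(6/(fan_in+fan_out)),
biases zero.

**Plateau restarts.** Full-batch descent through saturating sigmoids
sometimes never leaves the ln 2 ≈ 0.693 cross-entropy plateau (all
outputs stuck at 0.5); whether it escapes depends on the random
initialisation. `train_classifier` therefore retries the whole
pretrain+fine-tune procedure from a deterministically derived seed
(config seed + 1000·k) when the final loss stays above 0.2 or training
accuracy below 0.85, up to 4 attempts, returning the last attempt
regardless. Late restarts progressively shed pretraining (full, full,
quarter, none): on datasets whose images are very similar — notably
bias-corrected ones, where the nuisance variance is gone — the
reconstruction objective can collapse the hidden code into saturated
near-constant features, after which fine-tuning is permanently stuck;
discarding the pretrained initialisation and fine-tuning the same
architecture from fresh random weights is then the only full-batch
route off the plateau. This is optimizer hygiene, not extra
information: it uses only the training data and a seeded stream.

All randomness flows through one `numpy` Generator per training run, so
identical configs yield bit-identical models.

## Synthetic phantoms

A phantom realises the additive model generatively on a 28×28 grid
(the ROI size the classifier consumes):

* **Geometry.** An elliptical lesion with margin radius
  `r(θ) = r0(θ)·(1 + A·sin(Kθ + φ))`, φ seeded. Benign: A = 0 (smooth
  margin). Malignant: A ∈ [0.2, 0.35], K ∈ {5..9} lobes, plus a
  boundary-dropout arc (5–25% of the perimeter) where the
  lesion/background contrast is blended to the midpoint, emulating the
  "missing boundary" appearance of malignant lesions.
* **Intensities.** Lesion ≈ 0.30, background ≈ 0.62 (jitter ±0.02).
  The ~0.32 contrast is deliberately only about twice the default bias
  amplitude: that is the regime in which inhomogeneity visibly degrades
  lesion conspicuity, which is the clinical situation the correction
  method exists for. Much higher contrast makes the bias cosmetically
  irrelevant; much lower contrast makes the foreground/background
  decomposition itself ill-posed (the darkest biased background becomes
  indistinguishable from the lesion).
* **Speckle.** Mean-one multiplicative log-normal noise,
  `clean · exp(N(0, σ²) − σ²/2)` with σ = 0.05 — a standard first-order
  ultrasound speckle surrogate.
* **Bias.** A random degree-2 surface scaled so its peak |P| over the
  grid equals `bias_strength` (default 0.15), added after speckle; the
  injected surface is returned as ground truth. Regressing
  (rendered − clean speckled) images on the monomial design matrix
  recovers the injected coefficients with R² > 0.99 at σ = 0, i.e. the
  generator is an exact instance of the correction model.

Datasets are drawn per-sample from one seeded stream (geometry,
intensities, bias coefficients, phantom seeds) and split stratified by
class; the default 74 benign + 96 malignant with test fraction 27/170
yields the 143/27 split used in the two-arm experiment.

What the phantoms do **not** emulate: acoustic physics (point-spread
function, attenuation, shadowing), spatially correlated speckle, real
margin morphology, and operator-dependent ROI placement. Passing tests
therefore demonstrate correctness of the algorithms under the stated
model, not clinical performance.

## Two-arm experiment

`run_experiment` trains two classifiers — one on the raw images, one on
the bias-corrected images — with the **same** split and the **same**
training seed, so the arms differ only in the correction, and reports
confusion counts and the five derived metrics per arm (positive class =
malignant; metric rounding for report tables is half-away-from-zero to
2 decimals). Every output (metrics.json, predictions, summary) is a
deterministic function of the resolved config.

On the default dataset the corrected arm scores higher: the bias fields
are a per-image nuisance that the classifier would otherwise have to
learn to ignore from ~143 examples. The margin of that comparison on a
27-image test set is a handful of samples, so on re-draws of the
dataset the direction holds on average but not invariably — an honest
reflection of how small single-split comparisons behave. The effect is
also structurally bounded: an additive degree-2 bias spans only a
5-dimensional subspace of pixel space, which a sufficiently flexible
classifier can partially project out on its own.

## Numerical choices and degenerate cases

* Sigmoid is evaluated in a branch-stable form; probabilities never
  overflow for |t| up to 1e3.
* Least squares uses `numpy.linalg.lstsq` (SVD-based, minimum-norm on
  rank deficiency).
* FCM distances are floored at 1e-12; a cell sample with no intensity
  spread raises a degenerate-bipartition error, which `correct_image`
  converts to the identity fallback.
* Metric ratios with 0/0 denominators report 0 with a logged warning;
  confusion totals of zero are an error.
* Ties at probability exactly 0.5 classify as malignant.
* 8-bit PNG output rounds `v·255` to nearest; the round trip is exact
  after one quantisation.

## Known limitations

* The "constrained" cell-based bipartition of the original correction
  literature is not fully specified in the sources available to us; the
  two-stage FCM here is our realisation and is validated only against
  the package's own phantoms.
* Whether bipartition and surface fit should iterate is an open choice;
  both single-pass (`max_outer_iter=1`) and alternating modes are
  supported.
* The SDAE is intentionally plain (no minibatching, momentum, weight
  decay, or adaptive optimizers); it is not a competitive modern
  classifier, it is the reference architecture under study.
* Absolute accuracies on clinical data are out of reach by design; the
  synthetic experiment supports directional claims only.
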