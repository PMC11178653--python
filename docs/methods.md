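# Methods

`surgflow` implements a semi-supervised pipeline for online recognition of
surgical workflow at several granularity levels (phase ⊃ step ⊃ gesture)
from synchronized video and bimanual robot kinematics. This note records the
models, their assumptions, the numerical choices, and what the synthetic
benchmark does and does not establish.

## The pipeline

Given demonstrations $d = 1..D$ with frames $t = 1..T_d$ carrying a visual
stream $m_{d,t}$, kinematic streams $k^l_{d,t}, k^r_{d,t}$ for the left and
right patient-side manipulators, and frame labels $y^g_{d,t}$ at each
granularity $g$, the three stages are trained independently:

1. **Time-contrastive encoder.** A base encoder $f$ maps each frame to a
   visual feature $v$; a projection head $g$ plus L2 normalization maps $v$
   to a unit embedding $b$. Triplets (anchor $t_a$, positive $t_p$ with
   $|t_p - t_a| \le r_p$, negative $t_n$ with $|t_n - t_a| > r_m$, all in
   one demonstration) are trained with the hinge loss
   $[\,\lVert b_{t_a} - b_{t_p}\rVert_2^2 - \lVert b_{t_a} - b_{t_n}\rVert_2^2 + \alpha\,]_+$,
   averaged over the batch. No labels are used. Downstream stages consume
   $v$, not $b$: the pre-projection feature retains more information than
   the normalized embedding.

2. **Multimodal VAE with product-of-experts fusion.** Each modality
   $x_m \in \{v, k^l, k^r\}$ has a Gaussian encoder $q_\phi(z|x_m)$ and a
   decoder $p_\Theta(x_m|z)$. Modalities are assumed conditionally
   independent given $z$, so the joint posterior is the product of the
   per-modality experts and a standard-normal prior expert: precisions add,
   means combine precision-weighted. The loss sums $M$ unimodal ELBOs (each
   modality reconstructed from its own prior-fused posterior) plus one joint
   ELBO (all modalities reconstructed from the fused posterior, with weights
   $\lambda_m$), each with a $\beta$-weighted KL to the prior. The unimodal
   terms stop one modality from dominating the shared code. With $M = 1$
   the loss is exactly twice the $\beta$-VAE loss; this degeneracy is tested.

3. **Online LSTM classifiers.** One single-layer LSTM per granularity maps
   the latent sequence to per-frame class probabilities
   $p(y^g_{d,t}\,|\,z_{d,1:t})$ with masked cross-entropy (unlabeled frames,
   value −1, and padding are excluded). Inference is strictly causal;
   prefix invariance is asserted exactly in the tests.

## Design choices where the design was open

- **Prior expert always in the product.** Both the unimodal and the joint
  posteriors include the N(0, I) expert. This makes subset inference
  (kinematics-only, visual-only) well defined and the $M=1$ degeneracy
  exact. The unimodal KL terms therefore use the prior-fused posterior.
- **Decoder likelihood.** Unit-variance diagonal Gaussian, i.e.
  squared-error reconstruction plus the $\tfrac{D}{2}\log 2\pi$ constant.
  $\lambda_m = 1$ for all modalities by default.
- **Variance positivity** via softplus with floor $10^{-6}$; one
  reparameterization sample per expectation during training; posterior
  means (no sampling) at inference and for validation loss.
- **Triplet ranges in sampled-frame units** at the 3 FPS training rate
  ($r_p = 6$, $r_m = 12$, i.e. 2 s and 4 s). The positive window is
  symmetric around the anchor; negatives come from the same demonstration
  only; anchors whose negative set would be empty cannot occur because
  demonstrations shorter than $2 r_m + 2$ sampled frames are skipped.
- **L2-normalization guard:** a row with pre-normalization norm below
  $10^{-12}$ maps to the first basis vector instead of NaN.
- **Transcript intervals** are inclusive-inclusive in 0-based frames
  (JIGSAWS convention); uncovered frames are −1 and excluded from losses
  and metrics.
- **Resampling is strided decimation** (30 → 3/5 FPS are integer strides),
  never interpolation.
- **Normalization** is per-channel z-scoring pooled over the training
  demonstrations of the current fold only, with population variance so that
  re-applying to the fitted set gives exactly unit variance; constant
  channels are centered, flagged, and not scaled.
- **Early stopping** (MVAE): epochs are 1-based; training never stops
  before `min_epochs` (25), stops once `patience` (15) epochs pass without
  a new validation minimum, and always at `max_epochs` (300); the
  best-validation weights are restored. The validation split is 10% of
  training demonstrations (by demonstration, not frame), seeded.
- **Modality ablation by subset inference.** The ablation experiment reuses
  one representation trained on all modalities and queries it with expert
  subsets via the product of experts, retraining only the classifier per
  subset. This isolates what each modality contributes to the *shared*
  representation and keeps the experiment cheap; retraining the MVAE per
  subset is the more expensive alternative and would also measure
  architecture effects.
- **Label budgets are per demonstration:** a seeded subset of training
  demonstrations keeps labels; the rest remain label-free but still feed
  representation learning. This matches how annotation effort is actually
  spent (whole recordings are annotated or not).
- **AD-accuracy boundary rule.** The transition-delay metric is macro
  recall where a frame within $d$ frames of a true segment boundary counts
  as correct if the prediction matches either segment adjacent to that
  boundary ($d$ = 500 ms × fps). The precise windowing convention differs
  between implementations, so it is isolated behind `MetricConfig`; with
  $d = 0$ the metric reduces exactly to macro recall, and it is monotone
  non-decreasing in $d$ (both tested).
- **Edit score** normalizes the unit-cost Levenshtein distance between the
  run-length-encoded label sequences by the longer of the two and clips at
  0: $100\,(1 - \mathrm{Lev}/\max(|S_{true}|, |S_{pred}|))$.

## No deep-learning framework

All networks (MLP encoders/decoders, the LSTM, AdamW) run on a compact
reverse-mode automatic-differentiation engine written on numpy
(`surgflow._autodiff`, `surgflow._nn`), in float64. Every operator and each
network type is verified against central finite differences in the test
suite. The models at desk scale are small enough that this is fast; the
engine is not intended for GPU-scale backbones (a large pretrained
convolutional backbone is outside its scope — the image path uses a small
im2col convolution stem instead).

## The synthetic benchmark

Real surgical datasets cannot ship with this package, so every experiment
runs on a generator whose ground truth is known by construction.

- **Workflow:** a semi-Markov chain over 6 gestures assigned to 3 steps in
  2 phases; left-to-right transitions (optional skips), per-gesture duration
  = min + Poisson(mean − min) frames (defaults 25 + Poisson(25) at 30 Hz,
  ~300 frames ≈ 10 s per demonstration). Step and phase labels are
  deterministic containment maps of the gesture state, so hierarchy
  consistency holds at every frame.
- **Kinematics (8 channels per arm):** first-order spring pull toward a
  per-gesture target pose, rate 0.35 per frame, Gaussian noise σ = 0.3 —
  smooth, autocorrelated trajectories with transition lag, like real tool
  motion at coarse scale.
- **Visual stream (32 features, or rendered 64×64 frames):** per-gesture
  prototype + within-segment progress × drift + Gaussian noise σ = 0.6. The
  drift term makes temporal position within a segment visible, which is the
  signal the time-contrastive loss exploits.
- **Complementarity:** gestures 4 and 5 share their visual prototype
  (separable only kinematically) and gestures 2 and 3 share their kinematic
  targets (separable only visually). A per-frame Bayes classifier on one
  modality therefore has a computable ceiling that the joint classifier
  exceeds; this is what makes the modality-ablation experiment meaningful
  rather than trivially saturated.
- **Users:** 8 users × 3 trials; each user has skill scalars (duration
  scale in [0.85, 1.2], noise scale in [0.9, 1.3]) creating the inter-user
  variability that motivates leave-one-user-out evaluation. Leave-one-
  supertrial-out (trial i of every user held out) is also implemented.

What the generator does **not** emulate: photorealistic appearance,
instrument articulation, occlusions, label noise, class imbalance of rare
gestures, or inter-demonstration workflow variation beyond durations and
skips. Passing the end-to-end checks therefore shows that the pipeline
recovers structure its stages are designed for — it does not predict
absolute accuracy on real surgical video.

## Problem sizes and run times

Experiments use the desk-scale configuration (`surgflow.desk_config`):
encoder hidden width 64, 32-dimensional v and z, LSTM hidden 64, 20
triplet-training epochs of 2048 triplets, MVAE early stopping in [10, 60]
epochs with patience 6, classifier 50 epochs at 5 FPS, and the first two
LOUO folds of the 24-demonstration benchmark. One fold's representation
stages train in ~30 s on one CPU core; each classifier trains in a few
seconds. The reference-scale hyperparameters (hidden {1000, 500}
projections, z = 500, batch 256, stopping in [25, 300], LSTM hidden 300,
70 epochs) remain the dataclass defaults of each stage config.

## Known limitations

- Subset inference probes a jointly trained representation; it is not
  identical to training a unimodal model from scratch.
- The LSTM classifiers use full-sequence backpropagation (no truncation);
  fine for ~10 s demonstrations, memory-hungry for hour-long procedures.
- The edit score is sensitive to single-frame flicker by construction;
  no post-processing smoothing is applied, deliberately.
- `infer_z` returns posterior means; downstream consumers that need
  uncertainty should use `MVAEResults.posterior` for the full belief.
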