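# Methods

This note records the models and procedures implemented in `buspool`, the
assumptions behind them, and the design decisions taken where the design
was genuinely open. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sequence-level decision model

A breast-ultrasound (BUS) study is an ordered sequence of grayscale frames
of one lesion. Each frame *i* receives a malignancy probability
`s_i ∈ [0,1]` from the frame classifier and a binary quality gate `w_i`.
The sequence score is the quality-gated mean

    S_M = (1/N_q) Σ_i w_i s_i,     N_q = Σ_i w_i,

and the sequence is labelled malignant when `S_M ≥ t` with `t = 0.5` by
default (a tie is malignant — the clinically conservative direction).
When `N_q = 0` the gated mean is undefined; the implementation falls back
to the unweighted mean over all frames and sets a `low_confidence` flag,
because a clinical tool must emit a score for every input. The flag is
also set when `|S_M − t| < 0.05` (configurable margin). The rationale for
gating is that shadowed, blurred or badly-gained frames carry scores that
are at best uninformative and at worst systematically wrong; removing
them from the average should not make the decision worse, and helps
whenever degraded frames mislead.

## Frame quality metrics

* **Brightness** — the mean pixel intensity on the 0–255 scale. The
  operating band is `[10, 30]`, closed at both ends: below 10 indicates
  dominant acoustic shadowing, above 30 over-amplification. The estimator
  is pluggable so an alternative can be registered without touching the
  gate logic.
* **Blurriness** — the population variance of the discrete Laplacian
  (4-neighbour stencil `[[0,1,0],[1,−4,1],[0,1,0]]`) of the frame smoothed
  by a normalized Gaussian kernel (σ = 1.0 by default, truncated at radius
  ⌈3σ⌉), with reflective boundary handling for both filters so that frame
  borders do not inject spurious gradient energy. Low variance means a
  blurry frame. The operating band is `[200, 300)` — half-open at the top:
  scores at or above 300 indicate noise/gain artifacts rather than sharp
  anatomy.

Both metrics are computed on the **native-resolution** frame by default
(`quality_on_resized=False`): resizing rescales the Laplacian-variance
measure, and the default bands are tied to native frames. The smoothing σ
and the band edges are recorded in every result JSON.

The gate is `w = 1` iff both scores lie inside their bands. Interval
endpoint semantics (brightness closed, blurriness half-open) follow the
band definitions above exactly; the tests pin 9.49 → reject,
10.0 → accept, 186 → reject, 299.99 → accept, 300.0 → reject.

## Frame classifier

A ConvNeXt-style convolutional network implemented from scratch on numpy
arrays (channels-last), with hand-written backward passes verified against
central finite differences:

* patchify stem: 4×4 convolution with stride 4 (non-overlapping), then
  LayerNorm;
* four stages with stage-compute-ratio (3, 4, 6, 3); between stages a
  LayerNorm + 2×2 stride-2 convolution downsamples and doubles width;
* each block: depthwise 7×7 convolution (same padding) → LayerNorm over
  channels at each spatial position → 1×1 expansion by 4 → GELU → 1×1
  projection → residual addition. The skip path is included: the block is
  otherwise not a residual block, and the zero-weight-identity property
  the tests rely on depends on it;
* head: global average pool → LayerNorm → linear to 2 classes; softmax
  gives the malignancy probability (class order: benign, malignant).

LayerNorm uses per-sample statistics `(a−μ)/(σ+ε)` with ε = 10⁻⁶ and
identity-initialized scale/shift, so outputs are independent of batch
composition. GELU defaults to the exact form `z·Φ(z)`; the cubic tanh
approximation is available as a config option and agrees with the exact
form to < 10⁻² everywhere tested. Not implemented because they are not
part of the described design: stochastic depth, layer scale, EMA weights.

Default widths are (96, 192, 384, 768) at 224×224 input; the **tiny
preset** (16, 32, 64, 128) at 64×64 keeps the full depth schedule and is
what every experiment in this repository trains. Weights initialize from
a truncated normal (std 0.02, ±2 std), biases/shifts at zero; all
randomness is seeded.

Checkpoints are single `.npz` files embedding the weights, the full
architecture config and a format version; loading validates both.

The depthwise convolution, exact GELU and Adam update are numba-JIT
kernels (the layer sizes involved are too small for vectorized numpy to
amortize its per-call overhead); each kernel has a numpy twin used when
numba is absent, and the suite asserts the two paths agree to 10⁻¹².

## Training recipe

Adam with β₁ = 0.5, β₂ = 0.99, starting learning rate 10⁻⁴, batch size 2,
cross-entropy loss `−Σ gt·log p` (natural log, probabilities clipped at
10⁻¹²), 40 epochs by default (10 in the desk-scale preset). The
best-validation-accuracy checkpoint is retained. Runs are deterministic
given the seed: one generator drives minibatch order and augmentation.

Augmentation is applied **offline**: the training set is expanded to the
originals plus `augment_copies` stochastically augmented copies of each
frame (default 1 copy for the desk-scale experiment), then trained on as a
fixed set. The stack: horizontal flip (p = 0.5), 90° rotation (p = 0.5),
isotropic rescale by a factor uniform in [0.8, 1.2] with center-crop/pad
restore, 3×3 median blur, and CLAHE (clip limit 4.0 on the 256-bin
convention — mapped to scikit-image's normalized `clip_limit = 4/256` —
with an 8×8 tile grid); the latter three are each applied with
probability 0.5. "Scaling with 0.2" is read as a ±20 % scale jitter; the
90° rotation is a discrete rotation applied with probability 0.5, since
no angle distribution is stated anywhere the stack is described.

Splits are always **sequence-level** (stratified 70/15/15): frames within
one scan are near-duplicates, and a frame-level split would leak test
information into training.

## Synthetic phantom generator

The generator emulates the B-mode phenomenology the pipeline keys on; it
is not an acoustic simulation and claims no BI-RADS realism.

* **Background**: mean level 18 (0–255 scale) multiplied by unit-mean
  gamma speckle with shape 4 (σ/μ = 50 %, the fully-developed-speckle
  regime), overlaid with sparse maximal-intensity point scatterers
  ("glints", density ≈ 4 %). The glints are the frame's sharpness
  carrier: the joint requirement that a clean frame sit in brightness
  band [10, 30] *and* blurriness band [200, 300) admits only
  high-amplitude sparse structure (any smooth texture bright enough to
  reach the Laplacian-variance band would blow the brightness ceiling).
  Glint density is rescaled by the background fraction so the expected
  glint count — hence the sharpness statistics — is independent of lesion
  size, and the hypoechoic lesion interior itself is glint-free (few
  scatterers).
* **Lesion**: a persistent star-convex region per sequence, re-speckled
  each frame with ≤ 2 px translation jitter. Class morphology follows the
  standard sonographic cues: benign lesions are smooth (spiculation
  amplitude 0.05), round-to-oval (axis ratio 0.85–1.0) and mildly
  hypoechoic (contrast −6); malignant lesions are spiculated (amplitude
  0.4, 8 spicules), elongated (axis ratio 0.45–0.65), markedly hypoechoic
  (contrast −14), carry 8–10 punctate echogenic foci
  (microcalcification-like discs, radius 2 px) and a heterogeneous
  internal echotexture (a smooth random blotch field raising patches of
  the interior back toward background level). Boundary spiculation and
  eccentricity alone proved insufficient for the desk-scale classifier to
  learn within the 10-epoch budget, so the generator uses the full
  standard cue set; the malignant-class glint density is slightly lower
  (3 %) to keep both classes' blurriness distributions centred in the
  operating band despite the foci's contribution.
* **Degradations**: acoustic-shadow band (bottom 70 % attenuated to 5 %),
  Gaussian motion blur (σ = 3), and gain errors (×0.28–0.35 or
  ×2.2–2.5). Each is calibrated to violate at least one default quality
  band (shadow and low gain break the brightness floor, high gain the
  brightness ceiling and blur band top, blur the blur floor).
  `generate_sequence` corrupts a requested fraction of frames with a
  random degradation and returns the flags; clean frames whose speckle
  realization lands outside the gate bands (a few percent) are redrawn so
  corruption flags match gate outcomes.

What the phantoms do **not** model: attenuation with depth, refraction,
elastography/strain signal, probe geometry, real lesion pathology.
Passing tests therefore demonstrate the pipeline's mechanics — gating,
pooling, training, explanation — not clinical performance on real BUS
data.

## Desk-scale end-to-end study

`buspool.experiment.run_experiment` generates 20 sequences per class
(15 frames, 64×64, 30 % of frames corrupted), splits 70/15/15 by
sequence, trains the tiny preset for 10 epochs (best epoch selected on
the quality-screened clean validation frames), and evaluates the val+test
sequences two ways: quality-gated pooling vs. plain mean pooling. Frame
accuracy is reported on clean holdout frames — corrupted frames are
excluded there because the quantity of interest is class separability,
not robustness to degradations (that is the pooling mechanism's job).
`run_multi_seed` averages the comparison over seeds;
`scripts/acceptance.py` runs five. Problem sizes were chosen so one study
completes in a few minutes on a single CPU.

## Numerical choices and degenerate inputs

* Population (biased) variance throughout the quality metrics; no sample
  correction is stated anywhere the variance is defined.
* LayerNorm divides by (σ + ε), not √(σ² + ε); its backward pass guards
  σ = 0 with a floor.
* Softmax is computed with max-subtraction; cross-entropy clips
  probabilities at 10⁻¹².
* `pool_malignancy` rejects empty and mismatched inputs; scorer outputs
  outside [0, 1] are a contract violation and raise.
* Metrics with zero denominators (e.g. precision with no positive calls)
  are reported as `None` with an `undefined` flag, never coerced to 0.
* AUC uses the rank statistic with average ranks, so ties contribute ½.
* Bilinear resizing goes through Pillow in 32-bit float mode and clips to
  [0, 255]; constant images are exactly preserved.
* Frame ordering on load is a natural sort (digit runs compared
  numerically), making `frame_2 < frame_10` regardless of zero padding.

## Known limitations

* Results on phantoms do not transfer to clinical data; the study-scale
  numbers (GPU training of pretrained backbones on a private clinical
  database) are out of scope by design.
* The brightness estimator is the mean intensity; the literature offers
  fancier no-reference estimators, and the pluggable hook exists for
  them.
* The gate recomputes per-frame quality at inference; no dataset-level
  quality analysis (distribution trimming) is implemented.
* Grad-CAM hooks the stage-4 output (after the last residual block); the
  `layer_id` is recorded in every map so alternative hook points remain
  distinguishable.
* Threshold tuning by grid search is deliberately not implemented; the
  decision threshold is a reported, configurable constant.
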