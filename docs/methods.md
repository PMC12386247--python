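# Methods

`pestfusion` implements a multimodal detector for crop pests and their
natural predators that fuses three sensor streams: RGB images, thermal
infrared images, and a low-rate environmental series (temperature in
°C, relative humidity in %, and a normalized light reading).  This
note records the model as implemented, the choices made where the
design was genuinely open, and what the bundled synthetic data can and
cannot establish.

## Problem setting

Field monitoring rigs capture hardware-synchronized RGB/thermal frame
pairs while DHT22/LDR sensors log one reading per second.  Targets are
small (a floor of 20×20 px is enforced on annotations), pests and
predators look alike, and the imaging conditions swing from bright noon
to foggy dusk — conditions under which each modality fails in its own
way.  The detector therefore (a) aligns the two visual modalities and
down-weights regions where they disagree, (b) lets the environmental
state decide how much to trust each modality, and (c) decodes pests and
predators with separate query sets so the rare predator classes are not
crowded out.

## Numerical core

No GPU tensor framework is used: the package carries its own
reverse-mode automatic-differentiation engine over float64 numpy arrays
(`pestfusion.autodiff`), with im2col-based 2-D convolution, batched
matmul, reductions, and the usual activations as primitives, plus a
small layer library and AdamW (`pestfusion.nn`).  Every primitive is
verified against central finite differences in the test suite.  The
engine favors exactness and checkability over throughput; all shipped
experiments run in minutes on one CPU core.

## Preprocessing

* **Occlusion simulation** `I'(x,y) = 0` for `(x,y)` in a rectangular
  region `R`, identity elsewhere.  For augmentation, `R` has area
  uniform in 2–20 % of the image and aspect ratio in [0.3, 3]
  (unspecified upstream; chosen to straddle typical leaf-blade shapes).
* **Brightness perturbation** `I'' = I + N(0, σ²)` with σ = 0.05 on
  [0,1] intensities by default, clipped back to [0,1] because every
  encoder assumes bounded input.
* **Sensor-to-frame alignment**: exact linear interpolation
  `ŝ = s_k + (s_{k+1}−s_k)/(t_{k+1}−t_k)·(t′−t_k)` under the literal
  bracketing precondition `t_k ≤ t′ < t_{k+1}`; queries outside the
  series raise instead of clamping, so silent extrapolation cannot
  occur.  The generator guarantees bracketing.
* **Min–max normalization** against training-set extrema, clipping
  out-of-range evaluation values into [0,1].  The extrema travel with
  the checkpoint so evaluation reuses training statistics.

## Architecture

**Encoders.** RGB and thermal images pass through separate shallow
stacks of `depth = 3` blocks (conv3×3 → InstanceNorm → SiLU; the first
two blocks have stride 2), then adaptive average pooling to the
declared `C×H×W = 64×64×64` grid.  The instance normalization is
load-bearing: without it the three-layer stack attenuates the image
signal to below one percent of downstream bias magnitudes and the set
predictor converges to an image-independent prior.  Arbitrary input
sizes are first resampled bilinearly to `4 × H` on the data side.  The
environment vector is lifted by a single affine layer to 64
dimensions.

**Cross-modal attention fusion (CMA).** Per local region of an 8×8
grid, the channel-pooled activation energy of each modality is
histogrammed (B = 16 bins over the shared min–max range, Gaussian
smoothing with bandwidth one bin, floor 1e-8, renormalized) and the
inconsistency scored as `D_KL(P_rgb ∥ P_ir)`.  Alignment weights
`w = exp(−D_KL/τ)`, τ = 1, multiply both streams; zero divergence
leaves features untouched and weights never amplify.  The statistics
are descriptive — no gradient flows through the histograms.  Each
stream is then projected to `C′ = 32` channels (1×1 reduction plus a
3×3 context branch), passed through a convolutional spatial gate
(7×7 conv on [mean; max] pooled maps → sigmoid), and exchanged through
bidirectional single-head cross attention over spatial tokens
(`Softmax(QKᵀ/√C′)V`, Q from one modality, K and V from the other).
A residual gate `out = orig + sigmoid(γ)⊙enh` (per-channel γ, init 0)
bounds each modality's influence, and a learned 1×1 merge of the two
gated streams yields the fused `C′×H×W` map.

**Environment-guided gate (EMA).** The last 8 interpolated,
normalized env vectors (1 Hz, ending at the frame time) are embedded
and passed through L = 3 layers of RMSNorm → linear(64) → depthwise
temporal conv (k = 3, same padding) → SiLU → SS1D, with a residual
connection around each layer (added here for trainability of the
stack; the SS1D core itself is exactly `h_t = A h_{t−1} + B x_t`,
`y_t = C h_t`, `h_0 = 0`).  `A` is diagonal with entries
sigmoid-bounded in (0,1), so the recurrence is stable at
initialization; `B` and `C` are dense.  The final `y_T` is mapped by
two linear heads to spatial logits (32×32) and channel logits (64),
whose broadcast sum, plus a learnable scalar bias initialized at +2,
is squashed by a sigmoid into the modulation gate
`g ∈ (0,1)^{32×32×64}`.  The positive bias is an open-gate
initialization in the spirit of the LSTM forget-gate bias: the gate
starts near 1 and attenuates nothing until the environmental signal
earns influence, so the gated model is not handicapped relative to an
ungated one at the start of training.  Fusion is the exact elementwise rule

    F_fused(i,j,c) = g(i,j,c) · [α·F_RGB(i,j,c) + (1−α)·F_IR(i,j,c)],

with α = sigmoid(a) learnable, initialized at 0.5.  Because the CMA
output lives on a 32-channel 64×64 grid while the gate is declared on
a 64-channel 32×32 grid, an explicit adapter (1×1 conv + 2× average
pool) moves the per-modality streams into the gate's domain; in the
tiny configuration the two domains coincide and the adapter vanishes.
The gate is applied to the post-CMA per-modality streams (pre-merge),
so both fusion mechanisms act, and a learned 1×1 merge of the CMA map
and the gated map feeds the head.

**Decoupled set-prediction head.** A DETR-style encoder
(N = 6 blocks, d_model = 256, 8 heads, FFN 256→1024→256) runs over the
fused map's spatial tokens with fixed 2-D sinusoidal positional
encodings; projected tokens are LayerNorm-ed before the PE is added so
content and position start at comparable magnitude.  Two independent
100-query sets (pest, predator) are decoded by separate M = 6-layer
decoders against the shared memory; branches never exchange
information, and gradients from one branch's loss are identically zero
in the other branch's decoder and MLPs (asserted in tests).  Shared
three-layer MLPs per branch emit sigmoid-normalized (cx, cy, w, h)
boxes and a softmax over 8 classes plus a no-object slot.

**Losses.**  Hungarian matching (scipy's solver, verified against
exhaustive permutation search) pairs queries with ground truth per
branch under the DETR cost
`λ_cls(1−p) + λ_bbox‖·‖₁ + λ_giou(1−GIoU)` with λ = (1, 5, 2).  The
total loss is `λ_cls L_cls + λ_bbox L_bbox + λ_giou L_giou + μ L_con`:
inverse-frequency-weighted cross entropy `−Σ ω_i y_i log p_i` over all
queries (`ω_i = N/(C·n_i)` capped at 10× the median, no-object weight
0.1), L1 and GIoU over matched pairs, and a supervised-contrastive
pest/predator term (L2-normalized embeddings, temperature 0.1,
μ = 0.5).  Deep supervision — the same loss applied to every decoder
layer's predictions through the shared MLPs — is on by default; at
desk-scale budgets the head does not converge without it, and the
reported `l_total` is always the final layer's loss.

## Training defaults

AdamW (lr 1e-4 at full scale, weight decay 1e-4), linear warmup (50
steps) followed by cosine decay, gradient clipping at 1.0, batch 4.
One integer seed pins weight init, batch sampling, augmentation and
data generation.  The desk-scale memorization experiment
(`pestfusion.experiments`) uses the tiny configuration (encoder
16×16×16, fused map 8 channels, gate 16×16×8, d_model 64 with 4
heads, 2+2 transformer layers, 12 queries per branch, head tokens
pooled to 8×8) on 32 scenes at 64 px with 2 targets each, for 500
steps at batch 16, lr 1e-3 held constant after warmup, augmentation
off (input noise only slows memorization of a fixed scene set), and
λ_cls raised to 2 for the experiment: with deep supervision the box
terms converge well before the classification confidence does, so the
lagging term carries extra weight there.  Package-level loss defaults
remain λ = (1, 5, 2).

## Synthetic scenes

The generator emulates the statistical structure of field data:
foliage-like smooth-noise backgrounds; targets as textured ellipses
with class-specific hue, aspect ratio and spot count (6 pest classes,
lady beetle, lacewing); boxes ≥ 20×20 px with pairwise IoU ≤ 0.3;
thermal warm-blob signatures over a cooler background; time-of-day ×
weather conditions that modulate brightness (evening ×0.4), contrast
(fog halves it and adds haze) and the sensor series (light drops for
evening/fog, humidity rises in fog); and 1 Hz env streams that bracket
every frame timestamp.  It does **not** model photorealistic insect
appearance, radiometric thermal physics, motion blur, registration
error between the modalities, or annotation noise — so passing tests
establish mechanical and mathematical correctness of the pipeline and
learnability of a structured 8-class detection task at desk scale, not
field accuracy.

## Evaluation

PASCAL-VOC-style greedy matching: per (image, class), detections in
descending score order claim the highest-IoU unmatched ground-truth
box at IoU ≥ 0.5.  AP uses all-point interpolation (11-point optional)
and mAP@50 averages per-class AP over classes with ≥ 1 instance;
classes absent from the ground truth are excluded rather than scored
zero.  A `group_map` collapses the 8 fine classes onto
{pest, predator} before scoring, mirroring the two-super-class reading
of the metric; both modes are first-class.  Per-condition reports
partition scenes by their time-of-day and weather tags.

## Ablation switches

* `use_cma=False`: channel concatenation + 1×1 conv replaces the CMA
  module; per-modality streams become plain 1×1 projections.
* `use_ema=False`: the gate is identically 1; only α mixes modalities.
* `use_reweighting=False`: α frozen at 0.5 and the KL alignment path
  disabled (distinct from the previous switch).
* `decoupled_head=False`: one shared query set and head over all
  classes.
* Modality subsets: a missing stream is replaced by a learned constant
  (feature map for thermal, env vector for sensors) so downstream
  statistics remain valid; RGB is always retained.

## Known limitations

* The histogram/KL alignment path is non-differentiable by design;
  the weights act as per-region constants within a step.
* The engine is single-threaded float64 numpy; the published-scale
  configuration is exercised for shape/consistency but not trained
  here.
* At desk scale the classification confidence of matched queries
  converges more slowly than box regression; scores of correct
  detections and residual queries overlap longer than they would with
  field-scale budgets.
* The tiny-scale experiment reports training-scene mAP — a
  memorization check of end-to-end trainability, not a generalization
  claim.

* Ablation orderings measured in the desk-scale experiment are noisy:
  with only 32 scenes and 500 steps, the gap between the full model
  and a single-module ablation can be smaller than the run-to-run
  spread across seeds, so a single seed's ordering should not be read
  as a module-contribution estimate.  Field-scale budgets are where
  module contributions separate cleanly.
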