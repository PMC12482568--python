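# Methods

This note records the models the package implements, the assumptions and
defaults behind them, what the synthetic generator does and does not
emulate, and the numerical choices a user should know before trusting or
extending the results.

## Dual-branch classifier

**CNN branch.** A five-stage residual network: a 7×7 stride-2 stem
convolution with 3×3 stride-2 max pooling, then four bottleneck stages with
strides (1, 2, 2, 2) — total stride 32 at every scale. The full preset is
the standard 50-layer bottleneck layout (stem 64; stage outputs 256, 512,
1024, 2048; blocks 3/4/6/3). One squeeze-and-excitation block follows the
final stage (not per-residual-block): global average pooling produces a
channel descriptor, a two-layer bottleneck MLP with reduction ratio r
(default 16, the conventional value; 4 in the reduced preset) and a sigmoid
yields per-channel gates in (0, 1) that rescale the map. The recalibrated
map is pooled again and a linear layer projects it to the shared embedding
dimension d. Bypass mode forces the gate to all-ones and reproduces the
no-SE baseline exactly. Input normalization uses configurable per-channel
mean/std, default (0.5, 0.5): it avoids importing dataset-specific
constants and maps [0, 1] pixels to [−1, 1].

**ViT branch.** Non-overlapping P×P patches are flattened and linearly
projected to D-dimensional tokens (P = 16, D = 768, depth 12, 12 heads at
full scale); a learnable [CLS] token is prepended and a learnable position
encoding added once. Encoder blocks are pre-norm (x + MSA(LN(x)), then
x + MLP(LN(x)) with GELU). The [CLS] state is captured after the *block
output* (post-MLP, post-residual) of each tap layer — taps index whole
layers, so the post-block state is the natural reading — and the tapped
states are averaged without additional normalization (raw post-block
states). Default taps {6, 9, 12}: three evenly spaced depths ending at the
final layer; the reduced preset (depth 4) keeps that pattern with {2, 3, 4}.
With taps = {final layer} the branch reduces exactly to a standard ViT.

**Fusion (token-aligned multimodal attention).** Concatenating the two
branch embeddings and projecting 2d→d yields a single joint vector, over
which self-attention would be degenerate (one token attending to itself).
The fusion therefore builds T = 3 tokens — the CNN embedding, the ViT
embedding, and the projected joint token — so the attention stages have a
real sequence to mix; a strict single-token mode
(`fusion.sequence_mode="single"`) is available for comparison. Two
attention stages follow: an MHSA stage with separate Q/K/V projections
(8 heads at full scale) and a token-alignment layer whose four steps are
LayerNorm, one *shared* linear projection used for Q = K = V, multi-head
attention, and an output projection. Both stages sit inside pre-norm
residual connections: the equations do not write residuals, but a stacked
attention module without them is unstable to train; the residual form is
ablatable (`fusion.residual=False`). Attention scales by √d_k with
d_k = d/heads (the per-head convention). Stage counts are configurable;
one of each is the default. The head applies ReLU, dropout (rate 0.5 at
full scale, 0.1 reduced; 0.5 is the common choice for such heads) and a linear map to class logits.

**Initialization.** Kaiming-normal weights throughout, with two
small-data stabilizers adopted after pilot training: the residual output
projections of the fusion stages start at zero (each stage is exactly the
identity at initialization and learns to deviate), and the ViT blocks'
attention-output and second MLP projections start scaled by 0.1. Without
these, the randomly initialized attention stack corrupts the branch
signals early in training and the fused model underperforms its own CNN
branch at desk scale. The SE gate's second layer also starts at zero, so
gates begin at the neutral σ(0) = 0.5 regardless of descriptor magnitude
(a large random descriptor would otherwise saturate the float32 sigmoid to
exactly 0/1). No pretrained weights are bundled; the package trains from scratch by
default, and externally pretrained branch weights can be loaded through
the state-dict interface.

## Training recipe

AdamW with weight decay 0.01, batch size 32, up to 50 epochs, early
stopping when validation *loss* fails to improve for 15 consecutive
epochs, checkpoint selection by best validation *accuracy* — stopping and
checkpointing deliberately monitor different quantities, so a model can
keep improving in accuracy while its loss plateaus. Learning
rate: linear warmup (default 5 epochs, a conventional length) reaching the peak exactly at the end of warmup, then cosine
annealing to zero. The full-scale peak is 2·10⁻⁴; the reduced preset uses
1·10⁻³, since the width-64 model tolerates and needs a larger step at
these batch counts (pilot runs at 2·10⁻⁴ converged too slowly to be
useful within a 30-epoch budget). Training refuses to start if the
leakage audit finds source images or patients shared between train and
validation sets.

## Data pipeline

Coordinates are 0-based (row, col) with half-open patch intervals.
Grid patching anchors a fixed cols×rows grid at (0, 0) in row-major order
(a 2048×1536 field with a 4×3 grid of 512 px gives 12 tiles); sliding-window
patching places fully contained patches at stride multiples
(per-axis count ⌊(dim − patch)/stride⌋ + 1; 700×460 at 224/112 gives 15).

The stratified image-level split operates on source images, so patches
never straddle subsets. Bucket sizes: validation and test get
round-half-down(fraction × class size), train takes the remainder — for
200-image classes under (0.7, 0.1, 0.2) this is exactly 140/20/40. When
every record carries a patient id, whole patients move between buckets
(greedy fill toward the same targets, met as closely as patient block
sizes allow), so the split never separates a patient's images; the exact
rounding above applies to patient-free data. The
patient-grouped k-fold uses scikit-learn's `StratifiedGroupKFold` twice:
once to form k patient-disjoint test folds, once within each remaining
pool to hold out a patient-disjoint validation part (1/5 by default).
`audit_fold_plan` and `audit_split` verify the guarantees rather than
assuming them.

Augmentation policies: `bach` (horizontal/vertical flips, 90° rotations,
±20 % brightness/contrast jitter, Gaussian blur σ ∈ [0.1, 1.0]),
`breakhis` (flips plus continuous rotations within ±10°, reflection
padding), and `geometric` (flips and 90° rotations only — the fixture
default, since photometric jitter destroys none of the synthetic cues but
slows convergence). Each transform fires with probability 0.5. The 90°
angle set for the `bach` policy preserves tissue statistics and avoids
border fill; `breakhis` uses continuous small angles because those images
carry meaningful orientation statistics at fixed magnifications. Jitter ranges and the application probability are configurable.

## Synthetic tile generator

The generator's purpose is statistical class structure, not visual
realism: eosin-pink low-frequency stroma, anti-aliased hematoxylin-hued
elliptical blobs as nuclei, and a per-tile lesion region whose area
fraction is drawn from (0.15, 0.30) and enforced exactly by thresholding
the layout's distance field at the drawn quantile. Inside the lesion the
stroma is darkened by factor 0.82 (a desmoplasia-like cue that makes the
region geometry legible to patch tokens while carrying no class signal
for a globally pooled extractor, because the lesion area is
class-independent). Classes are factorial: a local cue (blob radius 2.0
vs 3.0 px, densities scaled as 1/r² so blob coverage of the lesion is
equal and the texture difference is granularity, not darkness) × a global
cue (lesion layout). The 4-class set uses {clustered, ring}; the 8-class
set adds {scattered, banded}. Tiles are grouped into synthetic patients
for exercising grouped k-fold. Everything is a pure function of
(spec, seed, class, index).

What passing tests on these fixtures shows: the architecture can learn and
fuse two cue families, the pipeline bookkeeping is exact, and the
explanations concentrate on lesional tissue above chance. What it does not
show: performance on real H&E images — the fixtures have no stain
variability, no tissue-type confounds, no scanner artifacts, no
magnification mixture, and far lower intra-class variance than real data.
A generative-augmentation stage (an external class-conditional GAN
trained at 1024×1024 for 3000 kimgs, producing 100 synthetic images per
class from 1536×1536 center crops) is documented as a supported workflow
but not reimplemented; externally generated images can enter through the manifest,
and the `synthetic_train_only` convention — synthetic items confined to
the training split — is the recommended default when they do.

## Desk-scale experiments

The reference experiments (`histofusion.experiments`) run the reduced
preset (CNN stem 8, stage outputs 16/32/64/128, one block per stage;
ViT patch 12, dim 64, depth 4, heads 4, taps {2,3,4}; fusion dim 64,
4 heads) on 96-px tiles: sizes chosen so a 30-epoch run takes about two
minutes on one CPU core. The 4-class task (400 tiles, 70/10/20) is the
learning benchmark: the dual model reaches ≥ 0.9 validation accuracy
within 30 epochs. The ablation comparison runs on the 8-class task
(800 tiles): at desk scale the stride-32 CNN's receptive field covers the
whole 96-px tile, so *no* layout cue can be made invisible to the CNN-only
arm — on the easy 4-class task every arm saturates and the comparison is
uninformative. The 8-class task keeps all arms below ceiling; because a
single run's dual-vs-single margin is within seed noise, the comparison
repeats all three arms over three matched seeds (60 tiles per class) and
compares mean test accuracies — the repeated-runs protocol used for model
comparison throughout the package. Under those conditions the dual model
outperforms both single-branch arms. This mirrors the full-scale ablation
structure qualitatively; full-scale accuracy levels require the real
datasets and GPU-scale training and are not reproduced here.

## Explainability

Grad-CAM weights are spatially averaged gradients of the *pre-softmax*
class score (predicted class by default, true class by flag); per-layer
maps are ReLU-rectified weighted channel sums, hence nonnegative. Fusion
resizes each map bilinearly (pixel-center convention with edge clamping —
`skimage.transform.resize(..., order=1, mode="edge")`) to the target size,
averages with equal weights, and min-max normalizes to [0, 1]; a constant
fused map has no range and is returned as zeros with a warning. Default
target layers at full scale: stage-3 final block, stage-4 second block,
stage-4 final block (one defensible reading of "three representative
layers"; the set is configurable by name). At reduced scale stage 4 has one block and its 3×3
map carries almost no localization, so the three-layer default substitutes
the stage-2 final block, keeping three maps at three resolutions. Overlays
are exact convex combinations `Image·(1−α) + Heatmap·α` (α default 0.5)
using a documented piecewise-linear jet-like LUT:
R = clip(1.5 − |4x − 3|), G = clip(1.5 − |4x − 2|), B = clip(1.5 − |4x − 1|),
all clipped to [0, 1]. Localization is scored as IoU between the top-q
quantile region of the fused map (q = 0.2 default) and the binary lesion
mask, with the closed-form chance level p·m/(p + m − p·m) for independent
random regions of area fractions p and m as the reference.

## Statistics

Run comparisons use the paired t-test over matched run vectors (e.g.
seeds 0–9 on fixed splits) and the paired Cohen's d = mean(diff)/sd(diff),
with the conventional 0.2/0.5/0.8 interpretation bands exposed as labels,
never as decisions. Zero-variance differences make t undefined: the result
is flagged degenerate (t and p are NaN and marked, never silent). Families
of comparisons are corrected with Benjamini–Hochberg by default; Bonferroni
is available. Per-class "accuracy" is reported in both senses found in the
literature — one-vs-rest accuracy and recall — explicitly labeled.

## Numerical choices and degenerate inputs

- float32 throughout the network; softmax and cross-entropy use max-shift
  stabilization; the sigmoid is computed in its numerically safe form.
- LayerNorm ε = 1e-5: a zero-variance (constant) token normalizes to 0 and
  the output collapses to the learned shift.
- Majority-vote ties break by highest mean class probability among the
  tied classes, then lowest class id — fully deterministic.
- Batch statistics: batch norm uses per-batch statistics in training and
  running averages (momentum 0.1) in eval, so eval-mode outputs are
  batch-independent and bit-deterministic.
- Checkpoints are NumPy `.npz` archives of named parameter arrays with an
  embedded JSON config snapshot.

## Known limitations

- No stain normalization, no WSI pyramid reading, no windowed attention,
  no attention-based explanations for the ViT branch (out of scope).
- The NumPy engine is single-process and CPU-bound; full-scale training is
  not practical with it — the full preset exists to verify architecture
  contracts, and desk-scale conclusions come from the reduced preset.
- Fixture results bound what the tests can claim about real histopathology
  (see the generator section above).
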