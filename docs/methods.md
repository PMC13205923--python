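# Methods

## Scope and design stance

`nodulenet` implements a hybrid CNN–transformer nodule classifier for
chest radiographs together with its training protocol, weak-localization
metric suite, paired-model statistics, and a synthetic phantom generator
that makes every component testable at desk scale. The numerical core is
a purpose-built reverse-mode autodiff engine on NumPy (`nodulenet.nn`):
no GPU framework is assumed anywhere, and every hand-derived adjoint
(convolution, batch/layer norm, attention primitives, pooling, bilinear
resampling) is verified against central finite differences in the test
suite.

## Architecture

**Baseline.** Standard ResNet-50: 7×7/2 stem, 3×3/2 max pool, bottleneck
stages of depth 3/4/6/3 with widths 64/128/256/512 (expansion 4),
global average pooling, and a 2048→2 linear head. Convolutions carry no
bias (batch norm supplies the shift), giving 23,512,130 parameters at 2
classes and the canonical 25,557,032 at 1000.

**MST block.** At stage width `C`: layer norm → 2-head self-attention
(biased q/k/v and output projections, scaled dot product, dropout 0.1
on attention weights) with an inner residual, then layer norm → a
two-layer biased `C→C` MLP (ratio 1.0) with exact-erf GELU and dropout
after each layer. Feature maps larger than the 14×14 attention grid are
adaptively average-pooled before tokenization (one token per cell,
embedding width `C`) and the block output is bilinearly upsampled back.
There are **no positional embeddings** and the spatial-attention branch
is parameter-free: this is the unique simple layout whose per-stage
cost `6C² + 10C` reconciles the two model totals exactly
(Σ over C ∈ {256, 512, 1024, 2048} = 33,461,760 = 56,973,890 −
23,512,130); any positional embedding or a parameterized (classic
CBAM-style, convolution-carrying) attention module would break that
arithmetic. The token grid is average-pooled (not max) so that pooling
and bilinear upsampling form a near-adjoint pair.

**Residual fusion.** The fused output is
`F_out = X_s + Upsample(reshape(S_MLP))` where `S_MLP` is the *output*
of the MLP sub-layer, not a second token-stream residual sum. With a
token-level MLP residual the outer addition would re-inject
`Upsample(pool(X_s))` on top of `X_s`, and a block with zeroed
projections would no longer be an identity; the implemented form makes
zero-weight blocks exactly transparent (asserted bit-wise in the tests)
while keeping the attention sub-layer's standard inner residual.

**Spatial attention.** `gate = σ(mean over channels)` multiplies the
top-stage features position-wise before global average pooling (the
dual-branch reading: one gated path to the classifier, one map path
out). The emitted localization map is the gate bilinearly upsampled to
input resolution and min–max rescaled per image to [0, 1]. A constant
gate carries no spatial preference: the map is zeroed and flagged
degenerate rather than divided by a vanishing range.

**Probability convention.** The head emits two logits; the "nodule
probability" is the positive-class softmax component. The decision
threshold is 0.5 and exact ties classify positive — screening favours
sensitivity. The 2-logit head is required by the parameter arithmetic;
a genuinely single-logit sigmoid head would count 2,049 head parameters
instead of 4,098.

## Training protocol

* AdamW, lr 1e-4, decoupled weight decay 0.01 (applied uniformly,
  including norm parameters — no parameter grouping is claimed),
  betas (0.9, 0.999), eps 1e-8.
* Cosine annealing per epoch from the base rate to 0 across the run
  (the final epoch uses the minimum rate).
* 25 epochs, batch 16, seeds (42, 444, 916) for replicate runs.
* Weighted BCE with `w_c = N/(2 n_c)` recomputed from the (possibly
  minority-upsampled) training counts; probabilities are clamped to
  `[1e-7, 1 − 1e-7]` inside the logs. The printed weight pair
  1.7684/0.6971 corresponds to counts (1034, 2623).
* Freeze policy: backbone stem and stage *parameters* are frozen; MST
  blocks and the head remain trainable (33,461,760 + 4,098 trainable
  parameters on the full hybrid). Batch-norm running statistics are
  buffers, not parameters: they keep adapting in training mode,
  standing in for the calibrated statistics a previously fine-tuned
  backbone would carry. A full phase-A fine-tune of the baseline is
  supported simply by calling `train()` on it (all parameters
  trainable).
* Checkpoints are written whenever the validation loss improves;
  validation F1 at the checkpoint is recorded. ("Selection by lowest
  validation F1" would select the *worst* model; it is treated as an
  erratum for lowest validation loss.)
* Determinism: a single run seed derives the dropout streams, the
  shuffling generator and the augmentation generator; identical seeds
  reproduce loss traces exactly.

## Synthetic phantoms: what they emulate and what they do not

The generator targets the statistical structure of a NODE21-style
screening corpus, not radiographic fidelity:

* positive prevalence 1134/4882 ≈ 0.2323;
* mean boxes per positive 1476/1134 ≈ 1.30 (implemented as a ~30%
  chance of a second nodule);
* nodule diameters log-normal (median 46 px at 224-px reference,
  σ_log = 0.5, clipped to [10, 120]), putting ≈80% of boxes under the
  70-px small-nodule limit — matching the published test-set mix where
  171 of 217 positives are "small"; diameters scale with `image_side`
  so smaller desk-scale phantoms remain placeable;
* 1–3 images per patient (the real distribution is unpublished; this
  is a stated placeholder) and greedy stratified patient-level
  70/15/15 splits: positive-carrying patients are assigned first
  against positive-image targets, pure-negative patients then balance
  totals; over 100 seeds each partition's class counts stay within ±2
  images of their targets while no patient ever spans two partitions;
* images are a smooth thorax gradient, two darker elliptical lung
  fields, 6–8 sinusoidal rib bands, Gaussian noise (σ = 0.05), and
  Gaussian intensity bumps for nodules (bump σ = d/4, contrast 0.35 by
  default) with tight boxes of side d.

Augmentation (training split only, guard-railed elsewhere): resize to
the working side, horizontal flip p = 0.5, rotation ±7°, translation
±5% of the side, brightness/contrast ±10% (the source protocol says
only "small/mild/limited"; these conservative magnitudes are
configurable), channel replication to 3, and standardization with the
conventional natural-image statistics (0.485, 0.456, 0.406) /
(0.229, 0.224, 0.225). Minority upsampling duplicates positive training
rows to a requested factor or positive:negative ratio; duplicates are
re-augmented independently at load time.

A green test on phantoms establishes that the architecture, losses,
splits and metrics behave as specified — not that the model would reach
any particular sensitivity on real radiographs. Real-data properties
the phantoms do not carry: source heterogeneity, anatomy-dependent
difficulty (hilar blind spots), realistic rib/nodule confusability, and
inter-reader annotation noise.

## Numerical conventions

* float32 throughout the network; statistics in float64.
* Chi-square upper tail via `scipy.stats.chi2.sf` (regularized
  incomplete gamma), accurate far beyond the 4–5 decimals compared, so
  printed-value checks are pure rounding comparisons.
* Rates displayed at 1 decimal; statistics at 4; improvement rows are
  differences of the *rounded* rates, matching the published rendering.
  Raw full-precision values are always retained in machine output.
* Undefined metrics (zero denominators, single-run SD, zero discordant
  pairs) are `None` sentinels, never 0, to avoid silently deflating or
  inflating aggregates. Run aggregation uses the sample (n−1) SD.
* Bilinear resampling uses the half-pixel-centre (align_corners=False)
  convention; adaptive average pooling uses floor/ceil cell boundaries.
  Both are realized as separable row-stochastic matrices, so their
  adjoints are exact transposes.
* Boxes are 0-based, half-open `(x_min, y_min, width, height)`; the
  box centre is taken in pixel-centre coordinates and the image
  diagonal is the corner-pixel-to-corner-pixel distance, so a peak at
  one corner with a 1-px box at the opposite corner scores exactly 0
  peak proximity.
* Small-nodule rule is strict: a box qualifies if width < 70 *or*
  height < 70; a 70×70 box is excluded.
* McNemar orientation: `n10` counts images the proposed model got right
  and the baseline wrong.

## Localization metric definitions

The four attention-map scores (mass fraction inside the box union;
peak-in-union indicator, row-major first-occurrence tie-break;
`1 − d/D` peak-to-nearest-centre distance; inside/outside mean ratio)
are this package's own reconstructions chosen to be consistent with the
published value ranges (first three ≤ 1, focus a ratio > 1) and with
the stated avoidance of detector-style IoU endpoints. They are compared
against exhaustive pixel-loop oracles on 8×8 maps in the tests. All
four are invariant to positive rescaling of the map. Published
localization table values are therefore not reproduction targets here.

## Budget-driven scale choices

Heavier checks are scaled down rather than gated: the overfit smoke
test runs the full hybrid at 64×64 input (fully convolutional with
adaptive pooling, so the architecture and the stage-1 14×14 pooling
rule are unchanged) for 8 of the 25 protocol epochs — the measured
training loss is below ln 2 from the first epoch and decreases, so the
truncation only strengthens the check; split invariants are asserted on
manifest construction (rendering determinism is tested separately).

## Known limitations

* CPU-only: a full 224×224, 4882-image protocol run is out of reach;
  all protocol defaults are nevertheless implemented and tested at
  reduced scale.
* No pretrained backbone weights are bundled (and none can be
  downloaded); `pretrained=True` raises with advice rather than
  silently initializing.
* Phantom realism is deliberately minimal (see above).
* No object-detection heads, comparator backbones, early stopping,
  hyperparameter search, or distributed training.
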