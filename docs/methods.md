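# Methods

## Model

`epunet` builds inherently interpretable image classifiers with the
structure of a generalized additive model (GAM):

    g(E[Y | I]) = β + Σᵢ Cᵢ(Iᵢ; ηᵢ),   i = 1 … N

Each additive term is a CNN **sub-network** `Cᵢ = C²ᵢ(C¹ᵢ(·))` that sees one
**perceptual feature map** (PFM) `Iᵢ` of the input image: `C¹ᵢ` is a
conventional convolutional feature extractor ending in one 512-unit rectified
fully-connected layer, and `C²ᵢ` is a single affine unit with a tanh
activation, so every sub-network emits a univariate **Relative Similarity
Score** (RSS) in [−1, 1]. For binary problems the link `g` is the logit and
the prediction is `σ(β + Σ RSSᵢ)`; the pre-link score is confined to
[β − N, β + N]. For multiclass problems each head emits one score per class,
β is a vector, and the link is a softmax. The intercept β is a trainable
scalar initialized at zero.

Because the decision score is *exactly* the sum of the per-feature scores,
the explanation is the model, not a post-hoc approximation: the additivity
residual |logit(p) − β − Σ RSS| is asserted below 10⁻⁵ in the test suite.
The ensemble combination (score sum, intercept, link) is computed in float64
on top of float32 sub-networks so this contract holds even for saturated
probabilities; sub-network scores are summed in sorted order so that
permuting sub-networks together with their PFMs is bit-neutral.

## Perceptual feature maps

Four opponent maps are extracted per image, in this fixed order:

| name | definition | normalization |
|---|---|---|
| `light_dark` | level-3 approximation of the 2D DWT of CIE-Lab L, up-sampled to H×W | min–max to [0, 1] per image |
| `coarse_fine` | highest-frequency band of the level-1 2D DWT of L (diagonal subband by default), up-sampled | ÷ max abs, zero-centred [−1, 1] |
| `blue_yellow` | CIE-Lab b plane (b > 0 yellowness) | (b + 128)/255, fixed global |
| `green_red` | CIE-Lab a plane (a > 0 redness) | (a + 128)/255, fixed global |

Colorimetry is sRGB under D65 (the consumer-image standard). The wavelet
family defaults to Haar — the simplest quadrature-mirror filter pair, fully
hand-checkable — and is configurable; the transform is the **decimated**
multilevel DWT (each level halves resolution, `periodization` extension
keeps the halving exact for even sizes), after which the selected bands are
up-sampled bilinearly back to the input size. An undecimated variant is not
provided: the decimated-then-upsample reading matches the halving behaviour
the pipeline is designed around. The diagonal subband is the default
"highest-frequency" texture band; `horizontal`, `vertical` and an
absolute-sum option are exposed in `PFMConfig`. Chroma maps of achromatic
images are constant; `drop_constant_pfms` removes them so grayscale problems
automatically run with N = 2.

Normalization rationale: the sub-networks need inputs on comparable scales.
The chroma planes get a *fixed global* affine map so that hue sweeps remain
monotone across images (a per-image min–max would destroy cross-image
comparability of color); the wavelet maps are scaled per image, with the
detail band kept zero-centred so a featureless image yields an exactly zero
`coarse_fine` map.

## Reference architectures

`base_i`: three convolutional blocks — [2×conv64], [2×conv128], [3×conv256],
each followed by 2×2 max-pooling and batch normalization; all kernels 3×3;
then the 512-unit FC layer and the tanh head. Input sizes must be divisible
by 8. `base_ii` prepends one extra block built around an inception module
(parallel 1×1/3×3/5×5/avg-pool+1×1 branches with widths 16/32/8/8,
concatenated to 64 channels; the pool branch uses 3×3 stride-1 *average*
pooling, whose backward pass is its own adjoint). Branch widths and the
average-pool choice are this package's defaults; any factory with the same
signature can be plugged into `build_epu`, which is how larger third-party
backbones would be used.

The layer stack itself (convolution via im2col + GEMM, pooling, batch norm,
dense, SGD with momentum) is implemented in NumPy inside `epunet.nn`, with
explicit backward passes verified against central finite differences in the
test suite.

### Initialization and optimization

Convolutions and the hidden FC layer use He-normal initialization; the final
univariate heads are initialized near zero (σ = 0.1/√512) so the ensemble
starts at the GAM intercept — on balanced data the initial BCE is ln 2 and
the early gradient field is not saturated by the tanh heads. Training
minimizes one consensus cross-entropy backpropagated through **all**
sub-networks and β jointly at every step (no per-sub-network fitting), with
SGD (default lr 10⁻², momentum 0.9, batch 64). Batch-norm inference
statistics use an exponential moving average with momentum 0.7 — fast
enough to forget its initialization within the few dozen optimizer steps a
desk-scale run takes, which keeps eval-mode probabilities calibrated (a
slower average leaves a systematic offset in the RSS signs after short
runs). Augmentation is
orientation-only — horizontal/vertical flips plus 90° rotations (rotations
only for square maps) — applied to the precomputed PFM stacks; this is exact
for the chroma maps and approximate at image borders for the wavelet maps,
which we accept as augmentation noise. A seed fully determines
initialization, shuffling and augmentation draws; early stopping is off by
default. Non-finite losses raise a `TrainingError` with the epoch/batch/lr
context rather than continuing silently.

## Interpretable outputs

Every prediction carries three artifacts: the class probability, the RSS
vector (rendered as signed red/green horizontal bars; sign > 0 votes for
class 1), and one **Perceptual Relevance Map** per sub-network. A PRM is
built from the feature maps of a mid-depth convolutional layer (default: the
5th, the depth at which maps are still spatially specific but semantically
informative): each of the n maps is scored by the Shannon entropy of its
64-bin intensity histogram, the ⌈n/2⌉ highest-entropy maps are averaged
(ties break stably toward lower map indices; discarded maps provably never
influence the result), the average is thresholded by Kapur's
maximum-entropy criterion — the gray level maximizing the summed foreground
and background histogram entropies, i.e. the split with maximum information
transfer — with sub-threshold values zeroed, and the result is up-sampled
bilinearly to the input size (the binary mask with nearest-neighbour). A
featureless (all-constant) layer output yields an empty PRM rather than an
error. Multiclass RSS bars display each sub-network's tanh-squashed score
margin of the predicted class over the best other class — a display
convention of this package.

Global behaviour is summarized by per-class means ± standard deviations of
each RSS component over a labeled set (`global_chart`).

## Metrics

**Interpretability accuracy** applies to tasks where every perceptual cue
separates the classes in a known direction: the ground-truth label is
(+1,…,+1) for class 1 and (−1,…,−1) for class 0, the predicted label is the
elementwise RSS sign (sign(0) → +1), and the score is the mean Jaccard
agreement in percent. The Jaccard on sign vectors is computed as the
fraction of positions with agreeing sign (this reproduces the 0%/100%
endpoints for fully opposite/identical vectors); an alternative reading that
treats each vector as a set of (position, sign) pairs is available via
`variant="signed_multiset"`.

**ROAD** (remove-and-debias) scores saliency-map faithfulness. For removal
fraction φ (default 0.2 per side), `R_low` removes the φ least-salient
pixels and `R_high` the φ most-salient (ties break by pixel index; as
φ → 0 both approach the original image); removed pixels
are imputed by *noisy linear* imputation — each imputed pixel equals the
mean of its in-image 4-neighbours, a sparse discrete-Laplace system solved
per channel with the retained pixels as boundary values, a tiny diagonal
regularizer (10⁻⁶, anchored at the retained mean) for components with no
retained neighbour, and additive Gaussian noise (σ = 0.01 on the unit
scale) for debiasing; a plain mean-fill fallback is available. With f(·) the
confidence for the class predicted on the original image, the score is
(cc_low − cc_high)/2 where cc_x = f(R_x) − f(I). A faithful map loses little
confidence when unimportant pixels are removed but collapses when the
salient ones are (cc_high ≪ cc_low ≤ 0), so higher scores mean more accurate
interpretations. A prediction's score is the mean over its PRMs, and a
dataset's the mean over images. When ROAD is used as an *evaluation* (the
faithfulness studies in the tests and the acceptance script), per-image
scores are additionally averaged over removal fractions {0.2, 0.4, 0.6},
the metric's standard multi-threshold reporting: a well-trained model is
saturated, so a single small fraction changes its confidence by ~10⁻³ and
the score's sign is dominated by imputation noise, while the multi-fraction
mean separates faithful from shuffled maps by two orders of magnitude.

## Synthetic benchmark

The generator emulates a two-class fruit discrimination task in which all
four opponent channels can carry signal: class 0 draws yellow elongated
crescents, class 1 red/green near-circles, on plain, value-noise, or
noise-degraded backgrounds, with randomized placement, size and rotation.
Object colors are specified in Lab around a shared midpoint
(L, a, b) = (62, 8, 24) with gaps ΔL = 9, Δa = 22, Δb = 21 scaled by the
per-channel `cue_strengths`; shape elongation and the crescent cut scale
with the `coarse_fine` strength. A strength of 0 makes the corresponding
class-conditional distributions identical by construction, so zeroing all
cues yields a provably chance-level task. Shapes are drawn analytically
with anti-aliased signed-distance edges, so exact object masks come for
free; generation is fully determined by the seed (per-image child streams).

What it does *not* emulate: natural-image texture statistics, occlusion,
lighting variation, within-class shape diversity, or the label noise of
photographic benchmarks. Passing the recovery and faithfulness tests on
this generator shows the pipeline is correct and self-consistent, not that
it reaches any particular accuracy on real endoscopic/dermoscopic data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the training studies at
16×16 pixels with 150 images per class (the null-separability study uses
300/class with a 500-image evaluation split to make the chance-level AUC
band statistically tight), 8–10 epochs, batch 64 — sizes chosen so the full
pipeline (pure-NumPy CNN training included) runs comfortably on a single
CPU while every asserted property remains scale-free. The generator default
is 400 images per class at 128×128, matching the scale such a benchmark
would normally be used at.

Other numerics: entropy histograms use 64 bins over each map's own range
(constant maps have zero entropy by definition); Kapur thresholding uses
256 bins and returns the upper edge of the background's final bin, so
`map ≥ t*` is the foreground and re-thresholding a refined map is a fixed
point; on ψ(t) plateaus (empty bins) the lowest maximizer is taken. DWT
sizes must satisfy min(H, W) ≥ 2^levels; default extraction needs images of
at least 8×8.

## Known limitations

- Pure-NumPy training is single-process and orders of magnitude slower than
  a GPU framework; the package targets method correctness and desk-scale
  experiments, not large-scale benchmarks.
- PFM orthogonality is approximate: Lab chroma and lightness are only
  decorrelated, not independent, and the two wavelet maps share the L plane.
- Orientation augmentation on precomputed PFM stacks differs from
  re-extracting PFMs of rotated images at image borders.
- The noisy-linear ROAD imputation solves an exact Laplace system; for very
  large images a multigrid or sparse-Cholesky approach would be preferable.
- Joint training places no penalty on the magnitude of uninformative
  sub-network outputs: on a color-only task the texture heads can drift to
  confident class-independent constants, so the chroma-vs-texture |RSS| gap
  can be thin even when the sign structure of the explanation is perfect.
  Magnitude comparisons between sub-networks are therefore weaker evidence
  than sign agreement or ROAD faithfulness.
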