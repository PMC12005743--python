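# Methods

This note documents the models, procedures and design choices behind
`phospsych`, in the order data flows through the pipeline.

## Synthetic faces

The generator (`phospsych.faces`) emulates the statistical structure of a
photographic face database — ≥16 identity classes, each rendered under 9
conditions (viewpoints −45/0/+45° × expressions neutral/joy/anger),
single-channel 0–255 intensities on a plain white 128×128 canvas — with
layered 2-D primitives: a head ellipse with a chin-sharpness warp and a
darker contour ring, a hair cap covering a parameterized fraction of the
upper head, mirrored eyes, a nose wedge and a curvature-modulated mouth.
The primitives deliberately realize the cues human observers report
using at low resolution (the facial outline and the hair mass).

**Identity sampling.** Each class is a vector of continuous uniform
draws (`sample_class_params`, deterministic in (seed, class id)).
Because raw uniform draws occasionally produce two identities closer in
pixel space than training jitter can discriminate,
`sample_distinct_classes` rejects and deterministically redraws a class
unless it keeps (a) an L∞ margin of 0.35 (on ranges scaled to [0, 1])
over the five heavy dimensions — skin tone, hair coverage, hair tone and
the two head semi-axes — and (b) a canonical-rendering pixel distance of
at least 30 (root-sum-square over pixels, divided by the canvas side)
from every accepted class. With both margins a pixel-distance 1-NN
classifier identifies high-resolution test images perfectly for every
seed tested, which is the generator's stand-in for the near-ceiling
high-resolution recognition of real faces.

**Conditions and jitter.** Viewpoint is realized as a per-row integer
horizontal shear plus constant shift (exact mirror pairs at ±45°);
expressions modulate mouth width/curvature and eye opening. Training
images add jitter: integer translation ±3 px, intensity gain ±10%
(measured from the white background, which therefore stays 255), and a
global feature-size factor ±5%. Training conditions are cycled
deterministically rather than drawn at random so every (class,
condition) cell is evenly represented — random draws can starve a cell
and break separability. The final smoothing uses a Gaussian of σ = 1.5
px: enough to soften primitive edges so that small translations cost
less pixel distance than identity differences do.

**What the generator does not emulate.** Photographic texture,
demographic attributes (age/gender), illumination direction, occlusions,
and the 4872-variant richness of real photo sets. Tests passing on these
faces show the pipeline's logic and trends, not photograph-level
difficulty; absolute accuracies are not comparable to values measured on
real face databases.

Design arithmetic helpers record the emulated source structure (400
identities × 27 variants) and the viewing geometry (a 7.33 cm stimulus
at 60 cm subtends ≈7°).

## Phosphene rendering

Stimuli are produced by `histogram_equalize → downsample_nn(P) →
quantize_levels(G) → render` (`phospsych.phosphenes`).

* **Equalization** maps v → round(255·cdf(v)), cdf taken over the whole
  image including the value's own bin; monotone, and a constant image
  stays constant.
* **Downsampling** uses nearest-neighbor sampling at pixel centers:
  output (i, j) reads input (⌊(i+0.5)H/P⌋, ⌊(j+0.5)W/P⌋). The
  pixel-center convention is symmetric and makes bit-exact tests
  possible.
* **Quantization** uses uniform bin edges on [0, 256): level k =
  min(⌊vG/256⌋, G−1), displayed at round(k·255/(G−1)) so outputs span 0
  and 255 and the map is idempotent at fixed G.
* **NGB** upscales the lattice to uniform square blocks. **GB** places
  one circular phosphene per cell (cell side c = canvas/P): profile
  q·exp(−r²/2σ²) with σ = c/4, truncated to zero outside r > c/2. The
  sampled profile is normalized so the brightest *pixel* of a cell
  equals the cell's quantized intensity q exactly — without this, cells
  with even side lengths would peak slightly below q because no pixel
  sits at the continuous center. σ and the truncation radius are
  configuration (`sigma_frac`), since only the qualitative shape
  (bright center, circular fall-off, kernel growing with cell size) is
  fixed by the stimulation physics.

Quantize-then-render order means "G gray levels" refers to phosphene
*peak* intensities; GB pixels between peaks take intermediate values.

## Recognition models

`phospsych.models` builds six families over a shared single-layer
classifier head (16, 4 or 2 units): PIXEL (linear on flattened pixels),
PCA (linear on k = 128 principal-component scores, via scikit-learn),
CNN_SHALLOW (one 5×5/stride-2 conv with 16 filters, max-pool 4, ReLU,
batch-norm), and scaled-down AlexNet-, VGG- and ResNet-style stacks (the
ResNet block: two conv layers plus a 1×1-conv shortcut). Layer widths
are behavior-level defaults, not replicas of any published table.

Training: Adam (lr 10⁻⁴, weight decay 10⁻⁴), batch 16, ≤30 epochs,
early stopping when validation loss fails to improve strictly for 7
consecutive epochs (patience configurable 7–10), learning rate ×10⁻²
on a 5-epoch validation-accuracy plateau, floor 10⁻⁸. Losses:
softmax cross-entropy or multimargin (margin 1, p = 1, averaged over
classes — the canonical definition). A fine-tuned variant trains on half
high-resolution, half highest-quality NGB images. Instances differing
only in seed form ensembles; ensemble means feed the downstream stages.

**Input normalization.** Models train on histogram-equalized
high-resolution images (`TrainConfig.equalize_input`, default on).
Equalization heads the stimulus chain, so test inputs always arrive
contrast-normalized; with the generator's piecewise-flat faces, training
on raw images creates a train/test intensity-distribution shift severe
enough to push trained CNNs to chance at every PIQ level. Photographic
images, with their continuous histograms, are far less sensitive to
this; for synthetic faces the normalization is required for the
qualitative degradation trend to appear.

All networks run on `phospsych.nn`, a small numpy engine (im2col
convolution, explicit backprop) gradient-checked against finite
differences; determinism is exact given the instance seed.

## Psychophysics

`phospsych.psychophysics` encodes the protocol: 36 subjects in 6 groups
of 6, one multiple-choice question set (MC1–MC6) per group, groups 1–3
assigned square-bitmap and 4–6 Gaussian phosphenes; 720 trials per
subject at the study scale (9 PIQ levels × 16 classes × 5 conditions),
each test image seen at most once per subject. Choice screens hold the
target plus 3 distractors drawn without replacement.

The response simulator gives subject s accuracy
p = 1/4 + (3/4 − λ)·sigmoid(a·log₂P + b·log₂G − θ_s), θ_s ~ N(θ, τ²).
Defaults a = 1.0, b = 0.5, θ = 7.0, λ = 0.05, τ = 0.5 put the cohort
near the 25% floor at (16 px, 2 grays) and near 70–85% at (64 px, 8
grays) with a log-linear rise — the shape reported for 4-way face
matching at these quality levels; they are synthetic-cohort
configuration, not measured constants. The first choice samples the
4-option posterior (mass p on the target, (1−p)/3 elsewhere);
confidence is "low" with probability 1−p; a low-confidence second
choice samples the renormalized remaining posterior, which fixes the
Top-2 statistics; response times are 1.4 s (protocol floor) plus
lognormal jitter. Trial tables round-trip through a validated CSV
schema compatible with per-trial exports of recorded experiments, so
real data can replace the simulator.

## Evaluation

Top-1/Top-2 percentages aggregate over any of {PIQ, class, condition,
observer}; ties in a model's second-best probability break toward the
lowest class index (deterministic). Observer-level outlier exclusion is
a single pass removing values > 2 population SDs from the cell mean;
population (ddof = 0) SD is the convention that matches the procedure's
worked examples. The one-sided Wilcoxon rank-sum test computes U with
midranks; p is exact (enumeration of all C(n, n_a) group labelings)
whenever n_a·n_b ≤ 200, otherwise a normal approximation with tie and
continuity corrections — the exact/approximate boundary is exposed
because either convention is defensible at the study's sample sizes
(10 instances vs 18 subjects).

## Extrapolation

The linear map regresses human mean accuracy on model mean accuracy over
the 9 tested levels (means over instances/subjects after exclusion) and
applies the line to model accuracy at the 16 untested levels, clipped to
[0, 100]. The shallow predictor is a 6 → h → 5 network (h = 3 for NGB,
4 for GB; ReLU hidden, linear output; MSE; Adam; batch 16; 3000 epochs;
9:1 split). Its input concatenates a model instance's per-condition
accuracies at one PIQ level with the instance–subject Pearson r computed
over all 45 shared (PIQ × condition) cells — the maximal shared domain,
chosen because the correlation's domain is otherwise unspecified.
Features and targets are standardized internally (the interface stays in
percent, per the reported tables); predictions are un-standardized and
clipped. `flag_dips` marks estimates lower than both grid neighbors
along either axis — the diagnostic that justifies preferring the linear
map when the nonlinear surface dips.

At the study scale the predictor's training set has 18 × 10 × 9 = 1620
rows. The 2880 stimuli needing estimates are the full grid's 3600 minus
the 720 shown to humans.

## Problem sizes in tests and the acceptance script

The shipped tests and `scripts/acceptance.py` run the pipeline at desk
scale as the package's own defaults for self-contained verification:
4 synthetic classes, 24–36 training images per class, ensembles of 1–3
shallow-CNN instances trained ≤12 epochs at lr 10⁻³, cohorts of 12–36
simulated subjects, 100 seeds for the linear-recovery study. Trend
assertions on these small ensembles use a 10-percentage-point
monotonicity tolerance (5 points for the larger simulated-human cells).
Study-scale quantities (16 classes × 1000 images, 10 instances) enter
through the design-arithmetic helpers, which need no training.

## Known limitations

* Absolute accuracies on synthetic faces do not transfer to photographs;
  only the pipeline's logic, trends and calibrations are validated.
* The GB kernel is a qualitative stand-in (σ = c/4, hard truncation);
  irregular phosphenes, electrode dropout and spatiotemporal dynamics
  are out of scope.
* The simulator models neither learning/fatigue across a session nor eye
  movements; condition-level difficulty offsets default to zero.
* Head-width masking to fewer options (`restrict_probs`) emulates the
  4-option chance level but not distractor-similarity effects.
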