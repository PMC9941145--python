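# Methods

## Scope and scale

The package implements a three-stage screening workflow for catheter
coronary angiography — candidate-frame selection, severity classification
with multi-view fusion, stenosis localization — together with the synthetic
data it trains on. Everything is sized for a single CPU: the nominal
512×512 / 60–200-frame regime is supported by configuration, but the
defaults, tests and reproduction script run a desk-scale profile (48–64 px
frames, 36–80 frames per video, tens of patients). The problem sizes used in
each experiment are stated below; they are the package's own choice of
scale, chosen so that every learned stage can be trained to convergence and
evaluated end to end in minutes.

## The synthetic generator

`angioscreen.synth` emulates the aspects of cine angiograms that the
workflow's stages must learn from, and nothing more.

**Vessel trees.** Each view is a 2-D projected tree of cubic-spline
centerlines: the right coronary artery (RCA) has exactly one primary branch
plus side branches, the left (LCA) at least two primaries, with the second
routed through a point on the first so the projected main branches interlap
— the left tree is morphologically busier, which is what makes the
coronary-type classifier learnable and left-side analysis harder. Radii are
constant per branch (3–5 px at desk scale); children start on their parent's
centerline.

**Severity encoding.** A stenosis is a cosine-profiled diameter reduction on
a branch: local width = base width × (1 − severity/100) at the lesion
center, so severity is a geometric, diameter-based quantity as in
quantitative coronary angiography. A 100% lesion leaves a visible gap and
renders the distal segment at much lower contrast. The rendered intensity of
the narrowed segment is *not* attenuated by default: a thin-but-dark strand
is the desk-scale cue the classifiers learn. (A Beer–Lambert-style option,
`render_vessel_layer(..., attenuate=True)`, scales intensity with lumen
diameter and is available for frame composition experiments; it makes the
narrowing an "absence" cue that tiny presence-detecting networks handle far
worse, so the default keeps the geometric encoding visible.)

**Contrast kinetics.** Per video, frames before the beginning contrasting
frame (BCF) and after the ending contrasting frame (ECF) show background
only; a linear ramp of (default) 4 frames washes contrast in and out, and
the plateau [BCF, ECF] renders the fully opacified tree. Frames outside the
ramp window are pixel-identical to the background render — these are the
"redundancy frames" the classification stage can harvest.

**Backgrounds.** A low-frequency Gaussian random field plus a few dark
elongated structures (catheter/rib surrogates). A bright compact marker
blob can be injected with class-dependent probability; see the redundancy
experiment below. All pixel values are quantized to 8-bit levels at
generation, so TIFF/PNG/DICOM round trips are bit-exact.

**Studies.** A synthetic patient is seven videos (4 LCA views: LAO/RAO ×
cranial/caudal; 3 RCA views), with per-artery lesion severities drawn once
and rendered consistently in every view of that artery while each view gets
its own projected geometry. Artery severity priors default to roughly
(25/57/18)% for LCA and (37/51/12)% for RCA across the three categories.
The artery label is the worst lesion category on the artery; the patient
label the worst artery label. Everything is deterministic in the seed.

What the generator does **not** model: true 3-D projection geometry (views
are independent 2-D draws sharing severities), cardiac or respiratory
motion, panning, ECG gating, photon statistics, or realistic X-ray
attenuation. Consequently, passing the recovery tests below demonstrates
that the pipeline's machinery — losses, architectures, decoding, fusion,
metrics, cross-validation — works end to end; it does not certify
performance on clinical angiograms.

## The neural-network engine

`angioscreen.nn` is a small reverse-mode autodiff engine on NumPy
(single-precision): dense/conv/pool layers, an LSTM cell, fused
softmax/BCE/focal/smooth-L1 losses, Adam and SGD. Convolutions are computed
as one channel-tensordot per kernel offset; 5×5 branches are factorised into
two stacked 3×3 convolutions; max-pool routes gradients to the first
maximal element. Initialisation: Xavier-uniform kernels, orthogonal
recurrent blocks per LSTM gate, forget-gate bias 1. Every operation is
verified against central-difference gradients in the test suite.

The shared backbone is inception-style: a stem convolution, then
`depth` blocks of parallel 1×1 / 3×3 / (3×3·3×3) branches concatenated,
each followed by 2×2 max pooling, a global pooling head, and a dense
classifier. The severity classifiers use a global **max** pooling head —
the decision "is there a focal narrowing anywhere" is an existence
question, and max pooling was decisively easier to train at this scale
than average pooling. The coronary-type classifier uses average pooling.

## Stage 1: candidate-frame selection

Backbone (width 4, depth 2, 32 px inputs) pre-trained per frame with binary
cross-entropy; its pooled embedding feeds a bi-directional LSTM over
32-step windows (stride 16, edge-repetition padding for short videos), whose
per-step forward/backward states concatenate into a one-hidden-layer
perceptron with sigmoid output. The sequence loss is a soft F1 per window,
`1 − 2Σpt/(Σp+Σt+ε)`, ε = 1e-7, averaged over the batch; only a
differentiable F1 variant is usable as a loss, and per-window computation
matches the chunked training layout. Nominal training lengths are 200
backbone / 100 sequence epochs at learning rates 1e-4 / 4e-5; the desk
profile uses 8 / 30 epochs at 3e-3 (Adam), which converges on the easy set.

Decoding: BCF/ECF are the endpoints of the longest run of per-frame
probabilities above threshold (default 0.5) — robust to isolated false
positives; up to 10 candidates are sampled evenly from the interval. The
report uses the mean of |ΔBCF| and |ΔECF| per video (a `max` reduction is
available), accepting at ≤ 3 frames and flagging errors at ≥ 10. Desk-scale
experiment (three seeds): 60 videos, train 40 / test 20 — mean errors
≤ 0.5 frames, accept rate 1.0.

## Stage 2: classification, redundancy training, fusion

2-CAT classes are {<25%, ≥25%}, 3-CAT {<25%, 25–99%, 100%}; boundaries are
inclusive at 25 and 100 is total occlusion. With redundancy on, background
frames join training as one extra category, subsampled to the mean target
class size; validation sets never contain them, and at inference the
redundancy score is dropped and target scores renormalised (which preserves
their ordering). Ties in the hard label go to the lower-severity category.

Fusion operates on probability vectors (a config flag switches to logits):
element-wise max over inputs one level below, then renormalisation. It is
permutation-invariant, idempotent on duplicates, and never lowers the raw
severe-class score when a view is added.

The **easy profile** for classification experiments renders one gently
curved vessel per 48×48 frame (no side branches, no clutter) with either no
lesion or a 70% narrowing over about a third of the branch. This profile
was chosen after inspecting failure cases at richer geometry: thin side
branches mimic the thin-segment cue and branch overlaps hide it, putting an
irreducible-ambiguity ceiling (~0.85 AUC) on tiny models. On the clean
profile, a width-6 depth-3 classifier (Adam 1e-3, 40 epochs, flip
augmentation, 120 images/class) reaches held-out AUC ≈ 0.98.

**Redundancy experiment.** The invariant mirrored is directional: with
label-correlated background clutter in training, redundancy training should
not hurt and typically helps held-out discrimination. At desk scale this
needs a confounder the tiny backbone actually prefers to the lesion cue; a
bright marker blob is learnable in a few epochs (the vessel cue needs ~20).
The experiment plants the marker in every diseased training image
(correlation 1.0), inverts the correlation held out, and gives redundancy
frames the marker at p = 0.5. A plainly trained model rides the marker and
collapses below 0.5 AUC held out; the redundancy-trained model cannot use
it (the marker predicts "background" as much as "diseased") and recovers
the vessel cue. Mean AUC gain over five seeds ≈ +0.3. Milder correlations
produce no measurable direction at this scale — the cost of the third class
(slower vessel-cue learning) then dominates — which is itself an honest
desk-scale finding documented here.

## Stage 3: localization

**Grad-CAM** uses the spec'd classic formulation on the last pre-pool
feature map of the trained severity classifier, upsampled bilinearly.
Boxes come from connected components of the map thresholded at half its
maximum (components under 4 px² dropped), scored by normalised peak. On the
clean single-vessel profile the activation peak lands inside the 25%-dilated
truth box in roughly two-thirds of cases.

**Anchor detector.** Five pyramid levels at strides 2–32: lateral 1×1
convolutions on the three pre-pool backbone maps plus two stride-2
convolutions; shared two-layer classification and regression heads over
7 K-means anchor shapes per cell (Lloyd's algorithm on annotated
(height, width) pairs, seeded, WCSS non-increasing per iteration, centroids
sorted by area). Matching: positive at IoU ≥ 0.5, background below 0.4,
ignored between, best anchor per truth forced positive. Losses are focal
(γ=2, α=0.25, classification bias initialised to −2) and smooth-L1 on
center/size offsets, normalised by positive count — RetinaNet defaults,
adopted unchanged. Training uses random horizontal/vertical flips with
pre-computed per-variant anchor targets. Inference: sigmoid scores
thresholded (default 0.3), top-200 decoded, greedy NMS at IoU 0.5, boxes
clipped to the frame.

**Scoring.** CAM boxes count at IoU > 0.2, anchor boxes at IoU > 0.5.
Global-sensitivity asks whether any detection hits the single most severe
truth lesion of an image; Sens_s/Spec_s use one-to-one greedy matching by
descending IoU; MSE is the mean squared center-to-center distance of matched
pairs scaled to the 512×512 nominal frame. Images without truth lesions are
excluded from global-sensitivity with their count reported.

The localization benchmark deliberately uses the *branching* geometry with
clutter (severity 60–100, one lesion per frame): on the single-vessel
profile both routes saturate at their thresholds and the comparison says
nothing. On the benchmark (60 training images, 60 epochs, three seeds) the
anchor detector reaches global-sensitivity ≈ 0.75–0.8 while the CAM route's
Sens_s stays ≈ 0.25 — the supervised route wins exactly where scene
complexity punishes coarse maps.

## Pipeline and cross-validation

`run_end_to_end` executes the stages under k-fold (default fourfold)
cross-validation stratified **by patient**: per-fold class proportions match
the global ones to within one patient, and no frame of a validation patient
is ever seen in training. Redundancy frames are harvested from pre-contrast
frames of training-fold videos only; a manifest flag `train_excluded` keeps
low-quality studies out of every training fold while still evaluating them.
The demo profile (8 patients, 2 folds, 64 px) trains one severity model per
coronary rather than one per LCA view — the per-view trainer is the same
function; grouping is the caller's choice at this cohort size. Reports carry
per-fold metrics, mean ± SD across folds, integrity flags (leakage,
redundancy containment) and a config hash; with the deterministic flag
(default) a rerun reproduces the report bit for bit.

## Metrics

Classification kernels are closed forms on the confusion matrix: accuracy;
Cohen's kappa (p_e = 1 reported as 0 with a flag); support-weighted F1 with
zero-support classes excluded; sensitivity as the ≥25% recall in 2-CAT and
macro recall in 3-CAT. AUC is the Mann–Whitney statistic with half-credit
ties; multiclass AUC is one-vs-rest macro-averaged; single-class truth sets
report AUC as unavailable rather than as a number. The suite checks every
kernel against brute-force pair-counting/loop oracles and against
scikit-learn.

## Numerical and degenerate-input choices

Boxes are 0-based half-open; IoU of a zero-area box is a validation error.
K-means reduces k with a warning when there are fewer distinct shapes than
clusters. Videos shorter than one window are edge-padded; a video with no
above-threshold frame yields an empty, flagged candidate set, counts as an
error case, and is excluded from mean-error statistics with its count
reported. An all-zero CAM yields an empty detection list; a zero-gradient
class is returned flagged. Score vectors reject negative entries; fusion
rejects empty input and mixed category schemes.

## Known limitations

Single-precision NumPy training is deterministic but slow; the experiment
scales are the largest that fit interactive budgets, and desk-scale
variance across seeds is visible in all recovery numbers. The generator's
background and contrast statistics are stipulated, not fitted to data. The
ImageNet-initialisation flag is accepted for interface compatibility but no
pretrained weights ship. CAM localization quality depends strongly on how
far the evaluation scenes sit from the classifier's training distribution —
exactly the weakness that motivates the supervised anchor route.
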