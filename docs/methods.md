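# Methods

This note records the models, conventions and numerical choices behind
`scopemotion`, and what the synthetic data does and does not establish.

## Frame ingestion

Frames are sampled on the grid t = k·Δ with Δ = 0.5 s by default — short
enough that inter-frame motion stays within the small-motion regime the
differential flow solver assumes, long enough that the scope moves
measurably between samples.  Each output frame is the *nearest* source frame
to its grid time (no temporal interpolation), and reported timestamps lie on
the grid.  A source of duration D (= frame count / fps) yields
⌊D/Δ⌋ + 1 frames.

Coordinates are 0-based (row, column), origin top-left, half-open ranges,
everywhere in the package.  Crop rectangles are (left, top, width, height);
the reference endoscopic crop for a 1920×1080 source is 850×750, horizontally
centred and top-aligned (`DEFAULT_CROP_1920x1080`) — the crop *size* follows
the reference acquisition protocol, the offset is a package default because
endoscope UI layouts vary.

Video files are decoded through imageio when an ffmpeg-capable plugin is
importable; a directory of PNG frames with a declared fps is the
always-available source and what the test suite uses.

## Informative-frame filter

Seven statistics per grayscale frame: intensity mean, variance, skewness;
gray-level co-occurrence correlation and contrast (32 levels, offset (0, 1),
symmetric and normalised — the canonical definitions for these feature
names); energy of the 4-neighbour Laplacian and energy of the
first-difference gradient, both as mean squared response per pixel (the
"per-pixel" normalisation keeps the features comparable across frame
sizes).  A constant frame gets skewness = correlation = 0 by convention
rather than an error.  The classifier is an RBF-kernel SVC on standardized
features, with C ∈ {0.1, 1, 10, 100} and gamma ∈ {scale, 0.01, 0.1}
grid-searched under 5-fold cross-validation.

## Horn–Schunck flow

Classical formulation: minimise Σ (Ex·u + Ey·v + Et)² + α²(‖∇u‖² + ‖∇v‖²).
Derivatives use the classical 2×2×2 forward-difference cube stencils; the
neighbourhood average uses the standard 8-neighbour kernel (1/6 cardinal,
1/12 diagonal); boundaries replicate edges.  The fixed-point iteration runs
for `n_iterations` (default 100) or until the mean absolute update falls
below `convergence_tol` (default 1e−4); α defaults to 1.

Input frames are luminance-converted and jointly rescaled so their maximum
intensity is 255.  This makes the result exactly invariant to uniform
intensity scaling and bit depth while keeping α = 1 on the intensity scale
classical practice assumes (with intensities in [0, 1] the same α would
over-smooth by two orders of magnitude).

The 2×2 stencils are anchored at one corner, so 90°-rotation equivariance
holds in the aggregate (mean flow) but not pixel-by-pixel; the tests assert
the aggregate form.  No pyramid: displacements beyond ~2 px are out of
scope by design, which the 0.5 s sampling interval enforces in practice.

Color encoding: hue = flow direction on the standard wheel (0° = rightward,
counter-clockwise positive in display coordinates, i.e. upward motion is
90°), saturation = |flow|/`magnitude_scale` clipped at 1, value = 1, so zero
motion renders white.  Any fixed bijective convention would do — the
classifier learns the mapping — but this one is decodable, and
`color_to_flow` inverts it exactly up to uint8 quantisation (hue resolution
degrades at low saturation, which is why round-trip tests use magnitudes
≥ 0.2 × scale).

## Direction CNN

Input 170×150 RGB by default (bilinear resize), three blocks of 3×3
convolution (valid, stride 1) → ReLU → 2×2 max pool with 16/32/64 filters,
one 128-unit hidden layer with dropout 0.5, softmax over three classes.
Filter counts, pool size and FC width are package choices — the task is a
color-distribution readout and does not need a deep network — and all are
configurable.  Implemented directly on NumPy (im2col convolutions through
BLAS); gradients are verified against numerical differentiation to ~1e−9
relative error.

Training: SGD with momentum at batch size 128 (smaller in miniature test
configurations), cross-entropy plus L2.  Hyperparameters are drawn by
randomized search — learning rate and L2 log-uniform over [1e−7, 1e−2] and
[1e−10, 1e−2], momentum uniform over [0.8, 0.99] (the momentum coefficient
is the only sensible reading of an SGD parameter on that range); each draw
trains briefly, the best validation accuracy wins and is retrained with
early stopping (default 30 epochs, patience 5, best-validation weights
kept, ties going to the later epoch so a lucky early epoch on a small
validation set cannot shadow the converged model).  Explicit
learning-rate/momentum/L2 values bypass the search when all three are set.
All randomness — initialisation, batching, dropout, search, folds — derives
from the config seed; inference is deterministic.  5-fold cross-validation
is stratified and accumulates validation predictions into a 3×3 confusion
matrix (rows = predicted, columns = true, order insertion/withdrawal/stop).

## Evaluation

recall_c = diag_c / column-sum_c, precision_c = diag_c / row-sum_c, F1 the
harmonic mean, overall accuracy = trace/total.  An absent class scores 0
with a warning rather than raising (small synthetic runs hit this).  The
packaged `table1_confusion.csv` transcribes the reference classifier's
published 5-fold confusion matrix (328,927 frames); recomputing metrics from
it reproduces the published per-class values to 3 decimals (one printed
precision value appears truncated rather than rounded; agreement is within
±0.001).  Report rounding: 3 decimals for fractions, 1 for percentages.

## Cecum locator

The movement classes map to x(t) ∈ {+1 insertion, −1 withdrawal, 0 stop}.
Candidates are the insertion→withdrawal transitions; stop samples do not
interrupt a transition (the scope commonly pauses at the cecum itself), and
a candidate is timestamped at its first withdrawal sample.

**Score.**  Each candidate τ is scored over the closed window
[τ − t/2, τ + t/2] by

    score(τ) = ∫ₜ area after τ − ∫ₜ area before τ ,

minimised over candidates, ties to the earliest.  For an ideal phase change
the score is −t (pure insertion area before, pure withdrawal after); brief
oscillations and isolated misclassified frames mix both signs on each side
and score near zero.  This contrast form — rather than the plain signed sum
over the whole window — is what makes the statistic a change detector: the
plain sum is ≈ 0 at a true phase change but ≈ −t at any candidate sitting
deep in the withdrawal phase, so a single insertion-misclassified frame
during withdrawal would always win, and the defect would *worsen* with
larger t, inverting the observed accuracy-vs-t ordering.  The contrast score
degrades gracefully with label noise and improves with t, matching the
reported behaviour of the method.  The plain signed window area remains
available as `window_area` and on each candidate.

Windows are time-based (dropping non-informative frames leaves gaps; areas
integrate actual timestamps, no imputation) and truncated at the signal
ends rather than discarding boundary candidates — the cecum can fall near
the end of a short recording.  A signal without any transition returns an
explicit no-estimate result.  t must exceed ordinary repetitive
back-and-forth movements, which rarely last beyond 10 s; 10/20/30 s are the
standard settings, and the same t defines the ±t/2 band within which an
estimate counts as a hit during evaluation.

## Timeline report

Bins [k·s, (k+1)·s) anchored at the first sample, majority label per bin, a
final partial bin kept if non-empty; majority ties resolve to the label of
the bin's temporally first sample among the tied labels.  Default palette:
insertion red (214, 39, 40), withdrawal blue (31, 119, 180), stop gray
(127, 127, 127) — three maximally distinct colors, configurable.  Rendering
(PNG, fixed square size, cecum tick, legend) is byte-deterministic for
fixed inputs.

## Synthetic data: what it emulates, what it does not

**Frame pairs** — band-limited textures (Gaussian-smoothed white noise,
default σ = 4 px) warped by an analytic field: uniform translation for flow
calibration (exact circular shift when integral), or a radial field about
the centre (|flow| ∝ radius, peak = `magnitude` at the corners) emulating
the zoom-like appearance of advancing/retracting an endoscope.  The analytic
field is returned as the oracle; the solver recovers shifts ≤ 2 px with
mean endpoint error < 0.3 px (measured ≈ 0.03 px).

**Degraded frames** — clean sharp texture vs Gaussian blur (σ 4–8),
darkness (2–8% intensity), saturation (90–99% of pixels clipped), and
directional streaks (15–31 px kernels): the degradations that make real
frames non-observable.  The informative filter separates these synthetic
classes essentially perfectly; the published accuracy on clinical footage
(99.4%) is a property of data this repository does not ship, so the
synthetic result shows the machinery, not clinical performance.

**Direction signals** — a single true phase change at `insertion_duration`
(the ground-truth cecum time), oscillations as (time, half-length) pairs
injecting opposite-sign runs (kept ≥ half-length + 15 s clear of the true
change so ground truth stays unambiguous), stops zeroing samples i.i.d.,
label noise flipping signs i.i.d.  Samples live on t ∈ [0, total), so a
600 s + 400 s scenario at 0.5 s has exactly 2,000 samples.  The evaluation
battery draws insertion 300–900 s, withdrawal 240–600 s, up to three
oscillations of half-length ≤ 5 s (full runs ≤ 10 s, the reported regime),
stop probability 0.15 and label-noise 0.08 — chosen a priori as a plausible
regime consistent with the qualitative description of real procedures
(frequent brief repeat movements, pauses, a mid-90s%-accurate classifier).
Real label noise is temporally correlated and class-asymmetric where this
generator is i.i.d.; hit rates on the battery (≈ 57–64% / 88–90% / ≈ 100%
at t = 10/20/30) therefore demonstrate the ordering and robustness of the
locator, not clinical accuracy figures.

**Flow-color classification dataset** — hue-separable by construction: the
scope axis is modelled at a fixed oblique angle so insertion produces a
dominant flow direction (+x, jittered ±15° per sample) plus a weaker radial
expansion, withdrawal its negation, stop near-zero flow; each moving class
therefore owns one hue family and stop is desaturated.  A classifier
reaching ≥ 99% here (measured 100%) validates the training pipeline, not
performance on clinical flow images.

## Problem sizes in the standard runs

The reproduction script and test suite run the CNN at a 50×40 input on 300
images per class (one-fifth held out), the locator battery on 200 signals,
the locator/brute-force equivalence on 1,000 signals of up to 2,000
samples, and the flow oracle on 96×96 frames — sizes chosen so a full run
completes in about a minute on one CPU while every statistic retains a
comfortable margin over its threshold.  The architecture accepts the full
170×150 input (exercised in the tests); accuracy on the synthetic dataset
is insensitive to the input resolution because the signal is a color
distribution.

## Known limitations

- No pyramidal flow: large inter-frame displacements are out of scope.
- The CNN is a small from-scratch implementation; it is single-threaded
  BLAS-bound and not meant for GPU-scale corpora.
- The locator assumes one dominant phase change; procedures aborted before
  the cecum yield a no-estimate or a spurious minimum.
- Synthetic generators are stylised (i.i.d. noise, analytic motion); none
  of the clinical accuracy figures can be reproduced without the original
  labeled videos.
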