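# Methods

## Pipeline model

A CE+NBI frame is modelled as dark curvilinear vessels on a bright,
smoothly varying mucosa background.  The pipeline assumes (i) vessel
contrast is strongest in the green band, (ii) illumination varies on
scales much larger than any vessel, and (iii) vessel centrelines are
recoverable as one-pixel-wide skeleton arcs.  Everything downstream is
geometry of those arcs plus gradient statistics of the detrended image.

### Detrending

Each row of the grey frame is decomposed with a db7 wavelet to 7
levels (symmetric boundary extension), the approximation coefficients
are zeroed and the row reconstructed; the same pass then runs over the
columns.  This subtracts the level-7 approximation in each direction —
for a 256-px side the removed trend lives at scales ≳ 2⁷ px.  Two
consequences worth knowing:

* the operation is linear, so feature F1–F3 scale behaviour is
  inherited from the histogram normalization, not the detrender;
* structures constant along an axis (an exactly horizontal or vertical
  line) are themselves "trend" for the pass along that axis and are
  attenuated.  Real vessels at generic orientations are unaffected;
  the synthetic generator draws orientations from a continuous
  distribution, so the measure-zero axis-aligned case does not arise.

Requesting 7 levels on images narrower than 2⁷ px is rejected; beyond
the boundary-free maximum depth the symmetric extension keeps the
reconstruction defined (the underlying library's depth warning is
suppressed deliberately).

### Vessel enhancement and skeleton

Frangi vesselness with σ = 1…8 px (step 1), dark-ridge polarity,
standard correction constants, per-pixel maximum over scales, rescaled
to [0, 1].  A numerically constant input short-circuits to a zero
response: the filter's scale-adaptive structureness normalization would
otherwise amplify float round-off into a full-scale response.
Binarization uses Otsu's threshold computed only over responses above
1e-3, so the flat background does not dominate the two-class histogram;
a constant foreground (already-binary response) is taken as all vessel.
Thinning is homotopy-preserving iterative thinning; the contract is the
one-pixel-width invariant (no full 2×2 block), not a specific mask
sequence, and thinning a skeleton again is a no-op.

### Segments and reference geometry

Junction pixels (≥ 3 skeleton neighbours) are removed before tracing so
crossing vessels split into simple arcs; arcs are traced from the
lexicographically smallest endpoint (closed loops are cut at their
smallest pixel) and kept when strictly longer than 20 px.  Each segment
gets reference point A at its path head and B one pixel along the row
axis.  A fixed baseline shared by all segments makes ANG a well-defined
polar angle of C about A; the convention is configurable, and reversing
a path moves A to the other endpoint (a documented asymmetry).

### Indicators

* **HGD** — central-difference gradients; pixels above the 75th
  percentile of nonzero magnitudes count as significant; directions
  span [0°, 360°) in 180 bins (2°); magnitude-weighted, unit-sum.  The
  360° span (rather than axial 180°) keeps the two opposite-gradient
  lobes of a parallel-vessel field distinct.
* **RIA** — eight rotations 0°…315° in 45° steps (360° dropped as a
  duplicate of 0°); each rotation expands the canvas with zero fill so
  nothing is cropped; one mean per row; profiles concatenated in angle
  order.
* **ANG/DIS** — exact per-pixel formulas; atan2 of (‖cross‖, dot) keeps
  obtuse angles unfolded in [0°, 180°]; C = A maps to distance 0 and
  angle 0.
* **CUR** — tangent direction per pixel by total least squares over a
  ±5-pixel window (truncated at ends), oriented along the walk, angles
  unwrapped, then averaged over ~3 windows (15 samples) before
  differentiating with respect to chord-sum arc length.  The moving
  average cancels the periodic staircase wobble of shallow digital
  lines (their tangent error is zero-mean) at a small cost in bias for
  tight curves.  Measured against analytic oracles: digital straight
  lines of any slope stay below 0.01 px⁻¹; digital circles of radius
  10/20/40 px read mean |κ| within 15/9/4 % of 1/r.  Signed curvature
  is kept internally (path reversal negates it); features use energy,
  variance and |CUR| peaks, all orientation-invariant.

### Peak detector

Local maxima with prominence ≥ 0.1 × signal range.  Onset/offset are
the nearest flanking local minima strictly below the peak (so a plateau
peak's own top is never its base), clipped at the signal ends; the
amplitude is the prominence; the width is the full width at half
prominence, which for a rectangular pulse equals the pulse width.  Peak
waveform energies are summed over the union of onset–offset windows:
adjacent peaks share a flanking minimum, and the union keeps the
peak-to-total energy ratio (F4) within [0, 1].  For curvature peaks an
absolute prominence floor of 0.02 px⁻¹ applies in addition: a bend of
radius ≳ 50 px is not a loop, and without the floor a long, nearly
straight skeleton would contribute hundreds of round-off-scale "peaks"
to F23/F24.

### Sign-change counting

Per-segment derivative by a 5-point quadratic Savitzky–Golay filter
(polynomial-fit edges); strict sign changes counted with near-zero
values skipped.  "Near zero" uses an absolute deadband per indicator:
0.5°/sample for ANG and 0.05 px/sample for DIS.  The deadband is the
pixel-quantization floor — a skeleton pixel a few tens of pixels from A
jitters the angle by a fraction of a degree, which is measurement noise,
not vessel geometry.  Without it, segments whose true derivative is
zero (straight vessels seen from A) count a noise crossing every few
samples and the ordered class paradoxically scores the most changes.

### Features, degenerate policies

F1–F24 are assembled in the fixed order HGD(F1–4), RIA(F5–8),
ANG(F9–14), DIS(F15–20), CUR(F21–24); the CSV header carries the names.
Cubic-fit error e_m is the RMS residual (SSE selectable); segments
shorter than 4 samples are excluded from the e_m aggregates.  Every
degenerate case — blank image, no peaks, no segments — yields 0, never
NaN, so classifiers always receive finite inputs.

### Classification

`svm_poly` is a degree-1 polynomial-kernel SVM over standardized
features — the polynomial kernel in its reference configuration is
linear, which suits this nearly linearly separable feature space;
`svm_rbf`, `knn` (Euclidean) and `rf` complete the set.  Grids: C and γ
over 0.01…1000 in decade steps, k = 1…10, tree depth 1…10 with 10…100
trees in steps of 5.  Grid search maximizes mean stratified tenfold-CV
accuracy, scanning in ascending parameter order and replacing the
incumbent only on strict improvement, so ties resolve toward the
simplest model.  Evaluation pools out-of-fold predictions into one
confusion matrix; multi-class sensitivity/specificity are
class-frequency-weighted one-vs-rest averages, AUC likewise from
decision scores (SVM) or class probabilities (kNN, forest).  SVMs
resolve multi-class by pairwise voting.  Standardization is fit on
training folds only; the forest is scale-invariant and skips it.
Reference hyperparameters (C = 1; C = 1, γ = 0.01; k = 3; depth 8 with
50 trees) are the optima reported for clinical feature tables and serve
as documented defaults, not tested assertions.

## Synthetic data: what it emulates, what it does not

The generator renders dark vessels (Gaussian cross-profile, σ ≈ 1.3 px)
on a bright background (0.8) with a low-order polynomial + vignette
illumination trend (amplitude 0.15), optical blur (σ = 0.8 px) and
additive Gaussian noise (σ = 0.02) — defaults chosen as plausible for
contact-endoscope magnification, since no quantitative morphometry of
the clinical classes is published.  Classes:

* *order*: 5–15 near-parallel lines, ≤ 3° orientation jitter, ~1 px
  wobble;
* *disorder*: the same family but each vessel's heading oscillates
  sinusoidally about the common orientation by 60–100° over 2–4
  periods (position = integral of heading).  Heading meanders — rather
  than perpendicular displacement of a straight line — are what make
  the distance-to-reference profile genuinely non-monotone, as varicose
  longitudinal vessels do;
* *very_disorder*: 25–40 arcs/curls of radius 4–12 px and span
  180°–396°, eccentricity 0.7–1.3.

Per-image RNG streams derive from (seed, class, index), so datasets are
bitwise reproducible and order-independent.  The generator does not
attempt photorealism: no cellular texture, no specular highlights, no
vessel-width variation along a vessel, no motion blur, and no
benign/malignant histopathology beyond the three disorder levels.
Passing the class-recovery benchmark therefore shows the pipeline
separates the *geometric* pattern classes it was designed around — not
that it reaches any particular accuracy on clinical images.

## Problem sizes and numerical choices

The default benchmark is 100 images per class at 256×256 with generator
seed 7 — large enough for stable tenfold CV yet ~2 minutes of compute;
property tests use 8–30 images per class.  Extraction of one 256×256
frame takes ≈ 0.4 s.  Noise-robustness is checked at σ ∈ {0.02, 0.08,
0.2}, where CV accuracy degrades monotonically (≈ 1.0 / 0.86 / 0.5 at
12 images per class).  Ties in Otsu thresholding, peak plateaus and
path tracing are all resolved deterministically; the whole feature path
is seed-free, and the only stochastic components are the generator and
CV fold assignment.

## Known limitations

* The deadband constants and the curvature prominence floor are
  quantization-scale heuristics; heavily subsampled or super-resolved
  images would need them rescaled.
* Curvature bias grows for radii approaching the tangent window
  (≈ 15 % at r = 10 px); radii below ~6 px are under-read.
* Closed skeleton loops are cut at an arbitrary (lexicographic) point,
  which splits one loop's curvature profile.
* Axis-aligned straight vessels are attenuated by the row/column
  detrender (see above); clinically irrelevant, but visible in
  hand-crafted fixtures.
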