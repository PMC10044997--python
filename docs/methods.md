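# Methods

`retirr` quantifies mid-peripheral retinal shape irregularity from swept-source
OCT B-scans and classifies eyes that have experienced a rhegmatogenous retinal
detachment against eyes with an uncomplicated posterior vitreous detachment
(PVD). This note records the model, the numerical conventions, the synthetic
data generator and its calibration, and the known limitations.

## The irregularity representation

A B-scan is a 16 mm × 6 mm cross-section sampled at 2047 × 3072 px. The
retinal contour is the depth trace z(x) of the retinal pigment epithelium
(RPE) across the scan, extracted as a minimum-cost path (below) and expressed
in millimetres. Processing per scan:

1. **Detrend.** Fit a least-squares quadratic z ≈ c₀ + c₁x + c₂x² and keep the
   residual r(x). The x² coefficient c₂ is retained as the scan's curvature
   feature (mm⁻¹ up to a factor 2).
2. **Transform.** Take the DFT of the residual and correct each modulus for
   the arc length L of the contour ("the length of retina imaged"):
   bin_k = |X_k| · Δx / L for k = 1..30, in mm² per mm of retina, i.e. mm.
   Bin k corresponds to k full periods across the 16 mm window (bin 4 ≈ 4 mm
   spatial period; bins 23/26 ≈ 0.6–0.7 mm). The regional irregularity of a
   scan is the sum of its 30 bins.

**Window convention.** The column grid is endpoint-inclusive
(x_j = j·16/(N−1), j = 0..N−1), so the final sample duplicates the periodic
boundary. The transform drops it, making the FFT window exactly 16 mm: an
integer-bin sinusoid of amplitude A then yields bin value exactly A/2 on a
flat contour. No window function is applied; the detrended residual is
treated as periodic, and leakage from non-integer-period structure is part of
the method. The normalization constant is configurable (`amplitude_factor`)
because the absolute scale convention of the original report cannot be
determined; scale cancels after per-feature standardization, so it affects
descriptive magnitudes only.

**What quadratic detrending does to the spectrum.** A full-period sinusoid is
*not* orthogonal to quadratics on [0, 16]: the fit absorbs most of bin 1
(up to ~90%), ~15% of bin 2, ~7% of bin 3 and ~4% of bin 4, and the removed
quadratic leaks into all bins. Consequently the analyzer recovers an isolated
anatomical-scale component at bins ≥ 4 within 5%, but in mixed spectra small
high bins can be dominated by leakage from strong low-frequency shape; the
summed irregularity over bins 4–30 survives within ~10%. Very large
amplitudes at high bins also lengthen the contour, and the arc-length
correction then depresses all bins — negligible at anatomical amplitudes
(tens of µm), significant only in stress tests. These are properties of the
method, not of this implementation; they are consistent with bins 2–3 being
unimportant for classification while bins 4, 23, 26 carry the signal.

## Segmentation

The RPE trace is the minimum-total-cost left-to-right path through the image,
one node per (row, column), edges connecting adjacent columns within ±16 rows,
free start/end rows. At the device geometry the pixel aspect is ~4:1
(dx ≈ 7.8 µm, dz ≈ 2 µm), so ±16 rows tracks contour slopes to ~4 mm/mm —
ample for in-window retinas — while still forbidding speckle-driven jumps;
a tighter ±5 bound caps the traceable slope at 1.25 mm/mm and forces
corner-cutting on irregular contours. Node cost is 1 − the min-max-normalized
intensity after Gaussian smoothing of the cost field only, with physical
widths (σ ≈ 4 µm axially, under half the RPE band; ≈ 20 µm laterally to
average speckle) so behaviour is resolution-independent — the path tracks the
brightest ridge, which in both the synthetic model and SS-OCT anatomy is the
RPE band. A gradient-edge cost was considered and rejected: it localizes the
band's *upper edge*, systematically offset by half the band thickness from
the band centre, which is what the ground truth and the intensity peak
define. Any constant offset is immaterial downstream (removed by
detrending), but the ridge cost also makes the segmentation oracle exact.
The forward pass is a vectorized dynamic program (running-minimum filter per
column); backtracking re-derives each predecessor argmin, ties resolving to
the topmost row. Images whose dynamic range falls below 0.1 raise a
low-signal error rather than returning a junk trace.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is checked.

**Images.** A contour is a quadratic base (default apex 3.6 mm, edges 2.9 mm)
plus sinusoids at integer bin frequencies with configured amplitudes and
phases, plus optional white positional noise (2 µm default). The renderer
draws a Gaussian RPE band (σ = half the 20 µm band thickness) centred on the
contour, two dimmer inner-retina bands 0.18/0.30 mm above it, and
multiplicative gamma speckle with mean 1 and shape 50 — the device composites
100 B-scan repetitions, so residual speckle contrast is low; halving the
shape doubles speckle variance for robustness tests. Intensities are clipped
to [0, 1].

**Cohorts.** Groups, counts and demographics follow the study population
(PVD 88, detachment 67, tear 53; group-wise age and axial-length means/SDs,
truncated to the observed ranges 47–84 y and 22.14–27.27 mm). Per eye and
region, the expected 30-bin total R is drawn normal around the regional base
with the region's observed coefficient of variation; per-bin amplitudes
follow a 1/k profile times gamma(4) noise, A_k = 2·R·w_k·ε_k. In the
inferior region 45% of the total is drawn instead on a low-frequency profile
(bins 2–6): its excess irregularity comes from wide, shallow localized
concavities several millimetres across, which are long-period features with
little slope. Regional bases
are the study's regional means scaled by 1/10 (up 0.604, down 0.970, temporal
0.606, nasal 0.601 mm): the study's absolute magnitudes are incompatible with
contours inside a 6 mm window under this package's normalization convention,
and only ordering and ratios matter after standardization. PVD eyes' bases
scale with axial length (slope 0.07 per mm), reproducing the weak positive
irregularity–axial-length correlation seen only in the PVD group. Realized
waveforms are rescaled if an extreme draw would exceed a 2 mm peak or a
2 mm/mm slope budget (the acquisition protocol guarantees in-window,
shallow-relief retinas; rescales are logged).

**Group effect.** Detachment eyes receive additive amplitude shifts on three
designated bins — superior bin 4, temporal bins 23 and 26, the features the
deployed classifier uses — with per-(eye, bin) lognormal magnitudes (mean =
configured shift, σ = 2.4). The heterogeneity is deliberate: a minority of
strongly affected eyes gives the detachment class extra *variance* as well as
mean on those features, which is what makes the fitted QDA score two-sided
(U-shaped) and median-centering necessary — the behaviour the real classifier
exhibited. Tear eyes get the same shifts scaled by 0.6 (their observed
detection rate is lower than detachment eyes').

**Calibration.** The shift means (0.052, 0.038, 0.034 mm on the bin-value
scale) and σ were calibrated by simulation against joint design targets:
elastic-net screening at n = 200/group must recover all three injected
features essentially always; the exhaustive QDA search must place an
all-true-feature model in its top-ranked shortlist in ≥ 90% of cohorts; and
default-cohort runs must land near the study's operating point (measured at
freeze, over 16–20 seeds: test sensitivity 0.55, specificity 0.92,
sensitivity > 0.4 with specificity > 0.75 in 18/20 runs, repeated five-fold
CV success 0.74 ± 0.04). The CV success runs somewhat above the study's
reported 0.66: the recovery requirements pin the group effect's strength,
and the synthetic signal model carries no anatomical nuisance variation, so
the classes separate a little more cleanly than the clinical sample — a
known limitation, not a tuning artifact.

## Feature assembly

Eyes are split 2/3 : 1/3 into training and test sets, stratified by
diagnosis; tear eyes form a separate second validation set. Within the
training set, each diagnostic group is sorted by axial length and dealt into
5 folds block-by-block with fresh random permutations of {1..5} (remainders
to distinct random folds), balancing diagnosis and axial length per fold.
Each training eye's 30-bin spectra are expressed as differences from the mean
spectrum of PVD eyes in the *other* four folds; test and tear eyes are
referenced against all training PVD eyes (training-only information — the
original report is silent on test-time referencing, and this choice avoids
leakage). The 126-entry vector is: up/down/temporal/nasal bin differences
(4 × 30), four curvatures in the same order, axial length, age — curvature
and demographics raw, since the reference subtraction is defined for
irregularity only. "Up" gaze images the superior retina, "down" the inferior.

## Classifier

Candidates come from elastic-net (α = 0.5) or LASSO regression of the numeric
label (PVD → 1, detachment → 2) on the standardized training matrix, penalty
at minimum 10-fold CV MSE — the regression-on-label form matches the original
report's "mean squared error" language. The exhaustive search fits QDA to
every nonempty subset of the top six candidates (by coefficient magnitude;
the original screening yielded exactly six) up to size 6 and ranks by
training sensitivity among models with training specificity > 0.90, the
asymmetry reflecting that a false detachment label is the costlier error;
parsimonious models (≤ 3 features) outrank larger ones, matching the stated
search goal, and the preference is configurable. If nothing clears the
specificity bar the ranking falls back to specificity, flagged.

QDA fits one Gaussian per class with its own covariance (ridge of
10⁻⁶·trace/d for conditioning) and empirical priors; prediction is the
maximum posterior, and the posterior probability of label 2 is the ROC score.
With class-specific variances the acceptance region for the tighter class is
a central band — the mechanism behind the U-shaped score. The deployed
default uses the three named features (vector positions 4, 83, 86); the
search machinery can rediscover them on synthetic cohorts.

Evaluation: 2×2 confusion matrix (sensitivity = detachment eyes labelled 2 /
all test detachment eyes; specificity = PVD labelled 1 / all test PVD eyes),
two-sided Fisher's exact test, and a class-stratified percentile bootstrap
ROC (5000 replicates by default) with optional median-centering
s → |s − median(s)| applied inside each replicate; per-threshold bands are
pointwise percentile intervals on a fixed false-positive-rate grid.
Descriptives: Spearman correlations of axial length with total and regional
irregularity (overall and per group), pooled-variance t-tests for group
contrasts, one-way ANOVA across the four regions with Tukey HSD on per-scan
values.

## Reference problem sizes and reproducibility

The reference pipeline configuration renders 256 × 384 px frames over the
same 16 × 6 mm window and segments them; full 2047 × 3072 rendering is
supported and used in resolution-sensitive unit tests, but the statistical
behaviour is resolution-independent once segmentation error is sub-pixel, and
the reduced geometry keeps a full cohort run (832 scans) to seconds. A faster
contour mode skips image synthesis entirely and analyzes ground-truth
contours; it is used where segmentation is not the quantity under study.
Every random stage (cohort, split, folds, selection CV, repeated CV,
bootstrap) takes an explicit seed from the run configuration; identical
configurations produce byte-identical artifacts.

## What passing tests do and do not show

The generator emulates the *assumed signal model* — a bright band on a smooth
quadratic trend with sinusoidal irregularity and stationary speckle — and
cohorts whose regional structure, axial-length coupling and group effect
match the study's reported magnitudes in ordering and effect size. It does
not model fan-beam geometry or sensitivity roll-off, pathology morphology
(detachment scars, buckles), eye-motion artifacts, segmentation failure modes
from media opacity, or inter-device differences. Passing tests therefore
demonstrate that the pipeline implements the method faithfully and recovers
known structure under the method's own assumptions — not that the classifier
would attain the same operating point on new clinical data. The original
classifier is sample-defined; other populations need their own training sets.

## Numerical and degenerate-input choices

- Detrending uses a raw-power least-squares quadratic (x ≤ 16 mm keeps the
  Vandermonde well conditioned); residual orthogonality to {1, x, x²} is
  maintained to < 10⁻⁸ relative.
- Path ties in segmentation resolve to the topmost row; costs are invariant
  to positive affine rescaling of intensity.
- Uniform-intensity or zero-contrast images raise low-signal errors; contours
  leaving the depth window name the offending column; non-uniform sampling in
  the spectrum step asks for resampling instead of silently interpolating.
- Negative regional draws clip at 0 and waveform-budget rescales are counted
  and logged.
- Empty elastic-net solutions return an empty candidate set with a warning;
  QDA refuses classes with fewer samples than features.
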