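# Methods

This note documents the models, conventions and numerical choices behind
`shgfb`, and what the synthetic benchmarks do and do not establish.

## The F/B measurement model

An ROI is measured as a co-registered pair of grayscale intensity images: the
forward-scattered SHG channel F and the backward-scattered channel B. The
pipeline computes, per ROI:

1. background subtraction: `max(I - b, 0)` with `b` a per-channel scalar
   (the mean of a no-sample frame from the same imaging session). The
   functions accept a full background frame as well; the scalar form is the
   default because a flat offset is what the synthetic phantoms plant and
   the contract floors at zero either way.
2. ratio image: `R = F / B` pixelwise; pixels with `B = 0` are flagged
   non-finite and excluded from every downstream mean rather than clamped —
   an epsilon floor would silently bias the mean, whereas masked fiber
   pixels should have `B > 0` by construction.
3. masked mean: `mean(R over {mask = 1 and R finite})`, i.e. the mean of
   per-pixel ratios, not the ratio of channel sums. The two differ under
   spatial F/B variation; the per-pixel mean is the quantity the masks are
   designed for.
4. calibration: division by the session's FITC reference F/B, applied at the
   ROI level. Calibration commutes with the 3-ROI average because the factor
   is constant within a session, and ROI-level application keeps every
   stored `FBResult` in calibrated units.
5. region aggregation: unweighted mean over the (typically 3) ROIs of one
   region type; survival analyses use `ln F/B`.

## Masking conventions

All three methods binarize with a strict `>` — ties at the threshold go to
background — and the F and B masks are combined by elementwise product, so a
pixel must be bright in both channels to count as collagen.

**Manual.** The threshold is supplied per image (manifest column), standing in
for a blinded observer; there is no interactive component.

**Otsu, scale 0.6.** `otsu_threshold` exhaustively minimizes the weighted
within-class variance `w_bg var_bg + w_fg var_fg`. Candidates are the exact
distinct levels for integer images and 256 evenly spaced levels over
[min, max] for float images; ties break toward the smallest threshold, which
makes the brute-force oracle comparison exact. The 0.6 factor multiplies the
threshold *value* before binarization. Note a consequence of the smallest-tie
convention on degenerate two-level images: the threshold lands on the lower
level itself, so scaling by 0.6 can pull the lower mode into the foreground.
On images with within-class spread (any realistic image) the threshold sits
between the modes and the 0.6 scaling merely admits dimmer fiber pixels,
which is its purpose.

**Adaptive, factor 0.6.** A pixel is foreground when it exceeds 0.6x the mean
of the square window centered on it (edge windows are clipped to the image;
means use the actual clipped pixel count). Bright-foreground polarity is the
only reading consistent with masking collagen, which is the bright structure.
A constant image therefore yields an all-ones mask (`c > 0.6 c`); this
degenerate behavior is documented rather than special-cased.

The window size is selected per image before masking: the image is
pre-binarized at 0.6x its global mean, and candidate sizes are scanned from
largest to smallest; a size is admissible when the *emptiest* fully-interior
window position still contains at least 5% nonzero pixels. The smallest
admissible size is returned — equivalently, one step above the first size
(scanning downward) that fits into a collagen-free region. If even the
largest candidate fits into an empty region, it is returned with a warning;
requiring window sums over every position makes the search exactly
enumerable, which the fixtures exploit. The default size sequence descends
from the largest odd number ≤ min(H, W)/2, halving to 9.

## Survival statistics

**Quartiles.** Patients are rank-ordered on ln F/B and split into four
contiguous groups, sizes as equal as possible with the larger groups at the
*lower* quartiles (n = 95 → 24/24/24/23), matching the bookkeeping used for
cohorts of this size. Ties are broken by a stable sort on (value, id) so the
assignment is deterministic.

**Kaplan–Meier.** Standard product-limit estimator; censor times are carried
on the curve for tick-mark rendering. With no censoring the curve equals the
empirical survival function (a test asserts this to 1e-12).

**Cox model.** The partial likelihood uses the Efron tie correction and is
maximized by Newton–Raphson with analytic gradient and Hessian, step-halving
on real likelihood decreases (a relative tolerance of 1e-9·|ll| absorbs float
noise near the optimum), and convergence at gradient norm < 1e-8. Covariates
are internally standardized for conditioning and coefficients rescaled on
exit. Coefficients exceeding 40 on the standardized scale abort with a
monotone-likelihood (perfect separation) diagnosis; a singular or
ill-conditioned information matrix aborts with a collinearity diagnosis.
Fits are cross-checked in the test suite against lifelines to 1e-6 and
against a naive grid search on an independently coded partial likelihood.

**Tests.** Nested models are compared by the partial likelihood ratio test
(`2 Δll` against chi-square). The two-covariate bulk+interface model reports
per-covariate drop-one LRT p-values — "does this covariate add information
given the other". The bulk-vs-interface comparison is a paired two-sided
t-test by default (the same patients contribute both regions). All p-values
are two-sided and uncorrected. The S-ODX split uses `< 26` vs `>= 26`.

## The relative-risk tree

The splitter is the one-step full-likelihood method: the Nelson–Aalen
baseline cumulative hazard Λ̂ is estimated once from the root sample and held
fixed throughout. A node with events d_i and baseline values Λ̂(t_i) has
relative risk θ̂ = Σd_i / ΣΛ̂(t_i) and deviance

    D = 2 Σ [ d_i log(d_i / (θ̂ Λ̂(t_i))) − (d_i − θ̂ Λ̂(t_i)) ],  0·log 0 = 0.

Splits are found by exhaustive search over all covariates and all midpoints
between adjacent sorted distinct values (vectorized by prefix sums — for the
node MLE the linear terms cancel and D = −2[Σ_ev log Λ̂ + D_ev log(D_ev/ΣΛ̂)]);
improvement is parent deviance minus summed child deviances, which is
non-negative by construction. Ties break toward the earlier covariate and
smaller cutpoint, so growth is deterministic and order-invariant.

Defaults: `min_node_size = 10`, `min_events = 3` per child, `max_depth = 3`,
`min_improvement = 4.0`. The improvement threshold sits near the 95th
percentile of chi-square(1), so null splits are usually rejected while a
planted step effect of realistic size passes easily; with a ~100-patient
cohort these controls allow the depth-2, three-risk-group shape that a
single dominant F/B cutpoint plus a genomic-score refinement produces. No
pruning or cross-validation is applied — the package reports a single
descriptive tree, and the splitter is exposed (`best_split`) as the
extension point for honest-estimate or ensemble methods. Leaves are ranked
by θ̂ to name risk groups (group 1 = highest risk). F/B enters the tree on
the ln scale, consistent with the survival analyses.

## Synthetic data: what it emulates, and what it does not

**Image phantoms.** Fibers are random-walk polylines (angular diffusion 0.12
rad/step) blurred to a Gaussian cross-profile (default width 4 px, peak
2000 intensity units), with optional slow multiplicative intensity modulation
(depth 0.3) emulating regional brightness heterogeneity. B = fiber +
background + noise; F = fiber × planted F/B map + background + noise. The
planted F/B is either constant or a smooth log-normal field (default mean 15,
log-SD 0.25 — the scale of calibrated tissue measurements). Noise is
shot-like: Gaussian with SD = noise_scale·√(signal+1), clipped at zero.
Default canvas 512x512 (the pipeline demo uses 128x128 for speed); ROI
physical scale is not modeled, since every operation is purely pixel-based.
Phantoms do **not** model SHG physics (phase matching, depth-dependent
scattering, polarization), detector PSFs, or tissue morphology; passing the
round-trip benchmarks shows the *estimator chain* is unbiased at realistic
SNR, not that real-tissue F/B is measured without systematic error.

**Cohorts.** Per patient, (bulk, interface) ln F/B is bivariate normal —
interface mean 2.9 (SD 0.4) above bulk mean 2.4 (SD 0.5), correlation 0.4 —
and S-ODX is normal (mean 22, SD 10) clipped to [0, 100]. Event times are
exponential with rate `0.04 · exp(β_int·lnFB_int + β_bulk·lnFB_bulk +
β_sodx·SODX)` per month, with independent exponential censoring (rate 0.005);
defaults β_int = −0.8, β_bulk = 0, β_sodx = 0.03 plant a protective
interface effect, an uninformative (but correlated) bulk measure, and
independent genomic risk, giving a realistic ~40–60% event fraction. A
second generator (`generate_tree_cohort`) plants a piecewise hazard — high
risk below interface ln F/B 2.65 (0.020/month), and 0.008 vs 0.002/month
above it according to S-ODX ≥/< 25.5 — the three-group structure the tree
should recover. Real cohorts differ in ways these generators ignore:
non-proportional hazards, informative censoring, covariate measurement error
correlated across methods, and clinical covariates; the benchmarks therefore
validate the statistical machinery, not any clinical effect size.

**Calibration records** carry a session FITC F/B, optionally with log-normal
noise; the demo pipeline plants session factors (1.0, 1.25) into the raw
image ratios and the calibration step divides them back out.

## Benchmark problem sizes

The acceptance script and heavy tests use: 100 random 8-bit images for the
Otsu oracle; 100 phantoms (128x128, noise_scale 2 ≈ SNR 22 at fiber peak,
masks > 2000 px) for the noisy round-trip; 1000 null replicates at n = 100
for LRT type-I error; 200 replicates at n = 300 for coefficient recovery and
Wald coverage; 200 replicates at n = 500 for two-covariate attribution; 100
replicates at n = 500 for cutpoint/variable recovery; 60 replicates at
n = 300 for the three-group structure; and a 12-patient demo for end-to-end
determinism. These sizes give binomial/simulation standard errors comfortably
inside the asserted bands.

## Known limitations

- The manual method's "blinded observer" is a number in a manifest column;
  no reader-variability model is included.
- Backgrounds are scalar per channel/session in the pipeline (frames are
  accepted at the function level).
- The tree reports descriptive risk groups; no bootstrap confidence for
  cutpoints, no cross-validated pruning, and no survival-forest ensemble
  (the splitter is the documented extension point).
- Mann-Whitney associations with clinical covariates and whole-slide
  stitching/registration are out of scope.
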