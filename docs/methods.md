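# Methods

## Measurement model

The thoracic spine on a lateral projection is modeled as a circular arc: the
centroids of Th4–Th12 are assumed to lie near one circle, and the kyphosis
angle is the central angle θ subtended at the circle center by the radii to
the Th4 and Th12 centroids. Fitting a single smooth circle through all nine
centroids deliberately averages over local irregularities (vertebral wedging,
osteophytes, detector jitter) instead of depending on two endplate lines the
way a manual Cobb measurement does. The Cobb-equivalent angle is the angle
between the circle's tangents at the two endpoints; by the tangent–radius
identity this equals θ exactly for points on the circle, so the conversion
matters only insofar as noisy endpoints are first projected radially onto the
fitted circle.

### Circle fit

Two objectives are implemented:

* **algebraic (default).** The Kåsa linearization: with coordinates centered
  on the data mean, solve the linear system `2a·x + 2b·y + c = x² + y²` by
  least squares; `center = (a, b) + mean`, `r = √(c + a² + b²)`. Closed-form,
  deterministic, exact for points lying on one circle, and exact through any
  three non-collinear points. It minimizes the *algebraic* distance, which at
  realistic noise biases the radius low on short arcs.
* **geometric-refined.** Levenberg–Marquardt minimization of the sum of
  squared radial residuals `Σ(dist(pᵢ, center) − r)²`, seeded by the
  algebraic solution. This is the maximum-likelihood fit under isotropic
  Gaussian centroid noise and is empirically unbiased in θ at the noise
  levels studied here; it costs an iterative solve.

The algebraic fit is the default for reproducibility (no iteration, no
tolerance knobs); the geometric fit is preferred when bias matters.
Collinearity is declared — and the scan QC-flagged — when the smallest
singular value of the mean-centered coordinate matrix falls below 1e−10 of
the largest (a scale-free test). `rms_residual` is the root-mean-square
radial residual of the returned circle.

### Angle conventions and QC

θ is always reported on the minor arc, in [0°, 180°]. θ uses the raw Th4 and
Th12 centroids ("radii connecting the circle center to the centroids"); the
tangent construction projects the endpoints onto the circle first. The two
choices differ negligibly at observed residuals, but they are kept distinct
so the chord-based and tangent-based routes can be compared.

Quality control refuses to emit an angle when

* any of the nine levels is missing (no interpolation — the scan is referred
  for manual measurement),
* the chain is collinear within tolerance (straight-spine limit, radius → ∞),
* any interior centroid (Th5–Th11) falls on the opposite side of the
  Th4–Th12 chord from the minor-arc midpoint (the chain is not convex toward
  the fitted arc, so a single arc is the wrong model).

All angle computations are invariant to translation, rotation, reflection and
uniform scaling of the input, so the image coordinate convention (origin
top-left, y caudal) never enters the result.

### Estimator variance: what 1 px of centroid noise buys

The dominant error source is *not* endpoint jitter but the uncertainty of the
fitted center/radius along the arc's symmetry axis. For the study geometry —
nine centroids spanning 45.3° on a 300 px radius with isotropic Gaussian
noise of 1 px — the Fisher information of the full arc model (center, radius,
nine angular positions; 12 parameters) gives a Cramér–Rao bound of
sd(θ̂) ≈ 1.76°, hence a mean absolute error of at least
√(2/π)·1.76 ≈ 1.4° for any unbiased estimator. The geometric fit achieves
sd ≈ 1.86° (near-efficient, bias ≈ 0.04°); the Kåsa default adds a small
positive bias (≈ 0.5° at these settings) from its radius underestimation.
Endpoint angular noise alone would suggest ~0.27° — a factor of ~6 too
optimistic; any accuracy claim for arc-based kyphosis measurement must budget
for the center/radius uncertainty. Consequently, at these noise settings the
40° threshold classification agrees with truth for ≈ 92% of scans (the
misclassified ones lie within ~2° of the threshold), and tightening either
number requires lower centroid noise or more vertebral levels, not a better
optimizer.

For the same reason, comparing two radial-residual minimizers to 1e−4 in
center/radius is only numerically meaningful for sufficiently curved arcs:
below ~40° of span at 2% noise the objective valley is so flat that float64
cannot localize the minimizer to that precision.

## Synthetic phantoms

`PhantomSpec` generates what the geometry module inverts: nine true centroids
at equal angular steps spanning exactly the requested angle on a circle of
the requested radius, centered in a 640×640 image with the arc convex toward
the image left (the anterior side of a standard lateral acquisition).
Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `true_central_angle_deg` | 45.3 | inflammatory-cohort mean angle |
| `radius` | 300 px | arc radius in a 640×640 frame |
| `centroid_noise_sd` | 1 px | detector positional noise, i.i.d. Gaussian per coordinate |
| `dropout_prob` | 0 | per-level missed-detection probability (scalar or per-level map) |
| `image_size` | (640, 640) | raster frame, intensities in [0, 1] |
| `vertebra_size` | adaptive | body spans 70% of the arc step, 0.6 aspect (see below) |
| `background_noise_sd` | 0.02 | additive Gaussian intensity noise |
| `blur_sigma` | 1 px | Gaussian blur before noise |

Cohort angles are drawn from a normal with the cohort mean/SD
(45.3° ± 7.8° or 35.2° ± 6.5°), truncated to [5°, 120°] to stay inside
geometric validity. Rendered vertebral bodies are bright rotated rectangles
with the long axis tangent to the arc; when no explicit size is given, the
body spans 70% of the centroid-to-centroid arc distance (the vertebral share
of a vertebra+disc unit), which keeps phantoms valid across the whole cohort
angle range at fixed radius. Explicit sizes are honored and rejected with
`SpecError` if neighbouring bodies would overlap. One `SeedSequence` fans out
into independent streams for centroid noise, render noise and the two
observers, so the same seed reproduces every artifact byte-for-byte and
adding one stage never perturbs another.

**Manual readers.** Each simulated physician reads
`true + bias + N(0, sd)` (default sd 1.5°). If the two readings differ by
≤ 2° the manual value is their mean; otherwise the disagreement is resolved
by a "consensus discussion", modeled as both readers re-reading with half
their noise SD and averaging — consensus reduces, but does not eliminate,
reading error. The half-noise redraw is a modeling choice; no quantitative
description of real consensus behavior exists to calibrate against.

**What the phantoms do not emulate.** Real DEXA texture (soft tissue, ribs,
scanner-specific intensity calibration), vertebral shape variation (wedging,
syndesmophytes, fractures), correlated detector errors, and reader error that
grows with deformity severity. Passing tests therefore demonstrate the
correctness of the geometry, evaluation and statistics machinery and the
noise response of the estimator — not clinical performance on patient images.

## Stand-in detector and evaluation harness

`detect_blobs` thresholds the image (default 0.5), takes connected
components, drops components under `min_area` (default 40 px²) and returns
tight boxes with confidence = mean interior intensity; exactly nine surviving
boxes are labeled Th4–Th12 in cranio-caudal order, any other count stays
unlabeled. It exists purely so the evaluation harness can run end-to-end on
images; it is not a vertebra detector for clinical data.

Evaluation follows the standard detection protocol: predictions sorted by
descending confidence greedily claim the unmatched truth box of highest
IoU ≥ 0.5 (one-to-one); unmatched predictions are false positives, unmatched
truths false negatives; image-level success requires every truth matched.
Truth boxes flagged as partially visible are ignored on both sides:
not false negatives, not in the IoU pool, and predictions whose only
above-threshold match is a partial box are dropped from the tally.
AP integrates the interpolated precision envelope over the 101-point recall
grid; AP@0.5:0.95 averages ten IoU thresholds (0.50 : 0.05 : 0.95). Mean
IoU ± SD is over matched pairs (population SD, as printed in detection
tables).

## Agreement statistics

Differences are automated − manual throughout.

* **Pearson r** measures linear association only.
* **ICC(A,1)** — two-way model, absolute agreement, single measure — is
  computed from the ANOVA mean squares,
  `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)` with k = 2 raters, and
  its 95% CI from the McGraw–Wong F-distribution bounds (Satterthwaite
  degrees of freedom computed in scaled form to stay finite as ICC → 1;
  degenerate perfect agreement returns a point interval). Cross-checked in
  the test suite against pingouin's independent implementation.
* **Lin's CCC** uses population (n-denominator) moments,
  `2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)`, per Lin's original definition.
* **Error metrics**: RMSE, MAE, median and 95th-percentile absolute error
  (linear-interpolation quantile — recorded so results are bit-reproducible).
  RMSE and MSE are distinct quantities and never conflated.
* **Bland–Altman**: mean difference and limits of agreement
  mean ± 1.96·SD with the n−1 SD.
* **Threshold diagnostics** at 40°: the manual classification is the
  reference condition; sensitivity/specificity/PPV/NPV carry Wilson score
  95% CIs (well-behaved at proportions of 0 or 1); zero-denominator
  proportions are reported as absent, never as 0. AUC is the trapezoidal ROC
  area of the continuous automated angle against the binary manual label
  (ties grouped); a constant score yields 0.5, and AUC is absent when only
  one reference class is present.

Display rounding (percentages to integers, angles to 0.1°) happens only in
the report serialization layer; all stored values are full precision.

## Numerical and design notes

* Exact inputs are recovered exactly: the Kåsa fit through noiseless arc
  points reproduces center/radius to ~1e−12, so angle recovery on noiseless
  phantoms is tested at 1e−6 degrees.
* The consensus threshold comparison is inclusive (`≤ 2°` agrees), matching
  the rule that only discrepancies *greater* than 2° trigger discussion.
* The 40° classification boundary is inclusive (≥ 40° is significant).
* Angles at the antipodal limit return 180° (parallel tangents).
* Problem sizes in the test suite and acceptance script (500-scan cohorts,
  1000 noiseless arcs, 100 noisy fit instances, 30 rendered phantoms) were
  chosen as the package's own study sizes: large enough that Monte-Carlo
  error is small against the asserted tolerances, small enough to re-run
  routinely.

## Known limitations

* The arc model is global: focal deformities (single-level wedge fractures)
  violate the convexity QC or inflate the fit residual rather than being
  measured; such scans are flagged, not quantified.
* Angle estimation error is bounded below by the information limit discussed
  above; claims of sub-degree accuracy at 1 px centroid noise on a 300 px
  radius are not achievable by any estimator, including this one.
* The stand-in detector assumes bright, well-separated bodies on a dark
  background and is unsuitable for real radiographic data.
* Observer simulation parameters (bias, noise SD, consensus behavior) are
  modeling choices, not fitted to reader studies.
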