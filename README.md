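# kyphometry

Automated thoracic kyphosis morphometry from vertebral centroids, with
synthetic spine phantoms, a detection-evaluation harness, and the full
method-agreement statistical protocol.

## The problem

Thoracic hyperkyphosis — exaggerated forward curvature of the thoracic spine —
is a hallmark of advanced axial spondyloarthritis and a target of clinical
monitoring. The clinical standard, the Cobb angle, requires a reader to draw
endplate lines on the end vertebrae of the curve; it is slow and
operator-dependent. When a detector (or a human annotator) supplies the
centroids of the nine thoracic vertebrae Th4–Th12 on a lateral scan,
the curvature can instead be measured automatically and reproducibly:

1. **Circle fit.** A least-squares circle is fitted through the nine
   centroids. The default is the Kåsa algebraic fit (closed form; with
   centered coordinates solve `2a·x + 2b·y + c = x² + y²`, then
   `r = √(c + a² + b²)`); an optional geometric refinement minimizes the sum
   of squared radial residuals `Σ(dᵢ − r)²` by Levenberg–Marquardt, seeded by
   the algebraic solution.
2. **Central angle.** The kyphosis angle θ is the central angle subtended at
   the fitted center by the radii to the Th4 and Th12 centroids, reported on
   the minor arc (θ ∈ [0°, 180°]); for points on the circle
   θ = 2·arcsin(chord/2r).
3. **Cobb-equivalent conversion.** The angle between the tangents to the
   circle at the two endpoints approximates the endplate-intersection angle
   of a manual Cobb measurement; for endpoints on one circle it equals θ
   exactly.

Scans with missing levels, collinear centroid chains, or chains that are not
convex toward the fitted arc are flagged `unsuitable` (referral to manual
measurement) rather than measured. Clinically significant kyphosis is an
angle ≥ 40°.

Because clinical lateral DEXA images cannot be shared, the package ships a
first-class synthetic-spine module: centroid chains on arcs of known angle
(cohort angle distributions 45.3° ± 7.8° for inflammatory-disease-like spines
and 35.2° ± 6.5° for controls), detector positional noise and dropout, raster
phantom renderings with ground-truth YOLO-format boxes, and two simulated
manual readers whose >2° disagreements are resolved by a consensus re-read.
On top sit a detection-evaluation harness (greedy IoU ≥ 0.5 matching,
precision/recall/F1, AP@0.5, AP@0.5:0.95, mean IoU ± SD, per-level missed
counts) and the agreement battery (Pearson r, ICC(A,1) with F-based 95% CI,
Lin's CCC, RMSE/MAE/median/95th-percentile error, Bland–Altman limits of
agreement, threshold diagnostics with Wilson CIs, ROC AUC).

## Worked example

```python
import kyphometry as k
from kyphometry import PhantomSpec, make_centroids, measure_kyphosis

spec = PhantomSpec(true_central_angle_deg=46.1, centroid_noise_sd=1.0,
                   radius=300.0, seed=7)
observed, truth = make_centroids(spec)
m = measure_kyphosis(observed)
print(m.central_angle_deg, m.cobb_equiv_deg, m.qc_flag)

df = k.make_cohort(200, 45.3, 7.8, spec, seed=11)
pairs = k.PairedAngles.from_dataframe(df)
rep = k.agreement_stats(pairs)
diag = k.diagnostics_at_threshold(pairs, 40.0)
```

prints (to chosen formatting):

```
true angle      : 46.1 deg
central angle   : 45.52 deg
Cobb equivalent : 45.52 deg
QC              : ok
fit radius      : 303.3 px, rms residual 0.648 px
classification  : significant

cohort n=200: r=0.966  ICC(A,1)=0.965  CCC=0.965
RMSE=2.05 deg  MAE=1.60 deg  Bland-Altman +0.37 [-3.59, 4.33] deg
threshold 40 deg: sens=0.94 spec=0.83 AUC=0.980
```

The single-scan angle (45.52°) deviates from the generating truth (46.1°) by
about half a degree — typical for 1 px centroid noise on a 300 px arc. The
cohort block shows the agreement battery between the automated angles and
simulated manual consensus readings: near-unity correlation and concordance,
errors of a couple of degrees, a small Bland–Altman bias with ±4° limits of
agreement, and high discrimination at the 40° threshold.

A CLI wraps the same pipeline:

```bash
kyphometry simulate --n 20 --angle-mean 45.3 --seed 7 --outdir out/
kyphometry detect --images out/ --outdir preds/
kyphometry angle out/centroids.csv
kyphometry evaluate --pred preds/ --truth out/ --out eval.json
kyphometry agree pairs.csv --threshold 40 --out agree.json
```

Exit codes: 0 success (QC-flagged scans are results), 2 usage/parse errors,
3 failed statistical preconditions.

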