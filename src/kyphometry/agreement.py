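"""Method-agreement and diagnostic statistics for paired angle measurements.

Compares an automated kyphosis angle against a manual (reference) Cobb angle
per scan, with the usual complementary battery:

* Pearson r — linear association only; blind to offset and scale.
* ICC(A,1) — two-way, absolute agreement, single measure (McGraw–Wong),
  computed from the ANOVA mean squares with the F-based 95% CI.  Penalizes
  systematic offsets, unlike r.
* Lin's concordance correlation coefficient (CCC) — correlation times an
  accuracy factor for bias against the identity line; population (n)
  moment denominators per Lin's original definition.
* Error magnitudes: RMSE, MAE, median and 95th-percentile absolute error
  (linear-interpolation quantile).
* Bland–Altman: mean difference (automated − manual) and limits of agreement
  mean ± 1.96·SD (sample SD, n−1 denominator).
* Threshold diagnostics at 40°: confusion matrix with the manual
  classification as the reference condition, sensitivity/specificity/PPV/NPV
  with Wilson score 95% CIs, prevalence, and ROC AUC of the continuous
  automated angle against the binary manual label.

Proportions with zero denominators are reported as absent (``None``), never
as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .errors import TooFewPairsError, ZeroVarianceError

__all__ = [
    "PairedAngles",
    "AgreementReport",
    "DiagnosticReport",
    "agreement_stats",
    "diagnostics_at_threshold",
    "confusion_from_counts",
]


@dataclass(frozen=True)
class PairedAngles:
    """Paired automated/manual angles, one row per scan; no missing values."""

    scan_ids: tuple[str, ...]
    automated: np.ndarray
    manual: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.automated, dtype=float)
        m = np.asarray(self.manual, dtype=float)
        if a.shape != m.shape or a.ndim != 1:
            raise ValueError("automated and manual must be 1-d and equal length")
        if len(self.scan_ids) != a.size:
            raise ValueError("scan_ids length mismatch")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(m))):
            raise ValueError("paired angles must be finite (drop QC rows first)")
        object.__setattr__(self, "automated", a)
        object.__setattr__(self, "manual", m)

    @property
    def n(self) -> int:
        return int(self.automated.size)

    @classmethod
    def from_arrays(
        cls,
        automated: Sequence[float],
        manual: Sequence[float],
        scan_ids: Sequence[str] | None = None,
    ) -> "PairedAngles":
        a = np.asarray(automated, dtype=float)
        ids = tuple(scan_ids) if scan_ids is not None else tuple(
            f"scan-{i:04d}" for i in range(a.size)
        )
        return cls(scan_ids=ids, automated=a, manual=np.asarray(manual, dtype=float))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PairedAngles":
        """Build from a table with scan_id, automated_deg, manual_deg columns,
        dropping rows with missing automated values (QC-flagged scans)."""
        sub = df[["scan_id", "automated_deg", "manual_deg"]].dropna()
        return cls(
            scan_ids=tuple(str(s) for s in sub["scan_id"]),
            automated=sub["automated_deg"].to_numpy(dtype=float),
            manual=sub["manual_deg"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class AgreementReport:
    pearson_r: float
    icc_a1: float
    icc_ci_low: float
    icc_ci_high: float
    ccc: float
    rmse_deg: float
    mae_deg: float
    median_ae_deg: float
    p95_ae_deg: float
    ba_mean_diff_deg: float
    ba_loa_low_deg: float
    ba_loa_high_deg: float
    n: int


@dataclass(frozen=True)
class DiagnosticReport:
    """2×2 diagnostic summary; proportions are None when undefined (zero
    denominator), CIs are (low, high) Wilson score intervals or None."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None
    ppv_ci: tuple[float, float] | None
    npv_ci: tuple[float, float] | None
    prevalence: float
    auc: float | None
    threshold_deg: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _icc_a1(x: np.ndarray, y: np.ndarray, alpha: float = 0.05):
    """ICC(A,1): two-way, single measure, absolute agreement, with the
    McGraw–Wong F-based confidence interval.  Raters are the two methods."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        return 1.0, (1.0, 1.0)
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:  # perfect agreement: degenerate CI
        return 1.0, (1.0, 1.0)
    r = icc
    eps = 1e-12
    one_minus = max(1.0 - r, eps)
    # the Satterthwaite dof v is invariant to a common rescaling of
    # (a*MSC, b*MSE); work with the scaled pair to avoid overflow as r -> 1
    scale = n * one_minus / k
    va = r * msc
    vb = (scale + r * (n - 1)) * mse
    v_den = (va**2) / (k - 1) + (vb**2) / ((n - 1) * (k - 1))
    if v_den <= 0:
        return float(icc), (1.0, 1.0)
    v = (va + vb) ** 2 / v_den
    if not math.isfinite(v) or v <= 0:
        return float(icc), (float(icc), float(icc))
    with np.errstate(invalid="ignore", divide="ignore"):
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    if not (math.isfinite(lo) and math.isfinite(hi)):
        return float(icc), (float(icc), float(icc))
    lo = max(-1.0, min(float(lo), float(icc)))
    hi = min(1.0, max(float(hi), float(icc)))
    return float(icc), (lo, hi)


def _ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation with population (n) moments."""
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    return float(2 * sxy / (sx2 + sy2 + (mx - my) ** 2))


def agreement_stats(pairs: PairedAngles) -> AgreementReport:
    """Compute the full agreement battery on a paired-angle table.

    Differences are taken as automated − manual throughout.

    Raises
    ------
    TooFewPairsError
        for fewer than 3 pairs (ICC needs n ≥ 3).
    ZeroVarianceError
        when either column is constant (r/ICC/CCC undefined).
    """
    if pairs.n < 3:
        raise TooFewPairsError("agreement statistics need at least 3 pairs")
    x, y = pairs.automated, pairs.manual
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError(
            "a measurement column is constant; correlation-type statistics "
            "are undefined"
        )
    if np.array_equal(x, y):
        r = 1.0  # pearsonr warns on exactly-identical input
    else:
        r = float(stats.pearsonr(x, y).statistic)
    icc, (ci_lo, ci_hi) = _icc_a1(x, y)
    d = x - y
    ad = np.abs(d)
    rmse = float(np.sqrt(np.mean(d**2)))
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return AgreementReport(
        pearson_r=r,
        icc_a1=icc,
        icc_ci_low=ci_lo,
        icc_ci_high=ci_hi,
        ccc=_ccc(x, y),
        rmse_deg=rmse,
        mae_deg=float(ad.mean()),
        median_ae_deg=float(np.median(ad)),
        p95_ae_deg=float(np.percentile(ad, 95)),  # linear interpolation
        ba_mean_diff_deg=mean_d,
        ba_loa_low_deg=mean_d - 1.96 * sd_d,
        ba_loa_high_deg=mean_d + 1.96 * sd_d,
        n=pairs.n,
    )


def _wilson(count: int, nobs: int) -> tuple[float | None, tuple[float, float] | None]:
    if nobs == 0:
        return None, None
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    p = count / nobs
    # guard float round-off: interval must contain the estimate, within [0,1]
    return p, (max(0.0, min(float(lo), p)), min(1.0, max(float(hi), p)))


def confusion_from_counts(
    tp: int, fp: int, fn: int, tn: int, threshold_deg: float | None = None
) -> DiagnosticReport:
    """Diagnostic report from a printed 2×2 confusion table (no angle data,
    hence no AUC).  Zero-denominator proportions are reported as None."""
    counts = (tp, fp, fn, tn)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("counts must be non-negative integers")
    tp, fp, fn, tn = (int(c) for c in counts)
    n = tp + fp + fn + tn
    if n < 1:
        raise ValueError("the confusion table must contain at least one case")
    sens, sens_ci = _wilson(tp, tp + fn)
    spec, spec_ci = _wilson(tn, tn + fp)
    ppv, ppv_ci = _wilson(tp, tp + fp)
    npv, npv_ci = _wilson(tn, tn + fn)
    return DiagnosticReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        ppv_ci=ppv_ci,
        npv_ci=npv_ci,
        prevalence=(tp + fn) / n,
        auc=None,
        threshold_deg=threshold_deg,
    )


def diagnostics_at_threshold(
    pairs: PairedAngles, threshold_deg: float = 40.0
) -> DiagnosticReport:
    """Threshold diagnostics with the manual measurement as reference.

    A scan is condition-positive when manual ≥ threshold and test-positive
    when automated ≥ threshold.  AUC is the trapezoidal ROC area of the
    continuous automated angle against the binary manual label (ties
    grouped); it is None when only one reference class is present.
    """
    if pairs.n < 1:
        raise TooFewPairsError("diagnostics need at least 1 pair")
    auto_pos = pairs.automated >= threshold_deg
    man_pos = pairs.manual >= threshold_deg
    tp = int(np.sum(auto_pos & man_pos))
    fp = int(np.sum(auto_pos & ~man_pos))
    fn = int(np.sum(~auto_pos & man_pos))
    tn = int(np.sum(~auto_pos & ~man_pos))
    base = confusion_from_counts(tp, fp, fn, tn, threshold_deg)
    auc = None
    if 0 < man_pos.sum() < pairs.n:
        auc = float(roc_auc_score(man_pos, pairs.automated))
    return DiagnosticReport(
        **{**base.__dict__, "auc": auc, "threshold_deg": threshold_deg}
    )


def bland_altman_plot(pairs: PairedAngles, path: str) -> None:
    """Write a Bland–Altman plot (mean vs difference, LoA dashed) to path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = pairs.automated - pairs.manual
    mean = (pairs.automated + pairs.manual) / 2.0
    md, sd = d.mean(), d.std(ddof=1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, d, s=12, alpha=0.6)
    ax.axhline(md, color="k")
    for y in (md - 1.96 * sd, md + 1.96 * sd):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel("mean of methods (°)")
    ax.set_ylabel("automated − manual (°)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def roc_plot(pairs: PairedAngles, threshold_deg: float, path: str) -> None:
    """Write the ROC curve of the automated angle vs the manual label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    labels = pairs.manual >= threshold_deg
    fpr, tpr, _ = roc_curve(labels, pairs.automated)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
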