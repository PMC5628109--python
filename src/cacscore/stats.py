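"""Agreement and evaluation statistics.

Covers the comparison machinery for ordinal risk categorizations and
continuous calcium scores: linearly (or quadratically) weighted Cohen's
kappa with a large-sample standard error, categorical accuracy with a
Wilson interval, the two-way absolute-agreement intraclass correlation,
the Wilcoxon signed-rank test for paired scores, z-comparison of two kappa
or accuracy estimates, and per-scan lesion detection metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .candidates import LesionCandidate


@dataclass
class ConfusionMatrix:
    """k x k table of reference (rows) vs test (columns) category counts."""

    counts: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] < 2:
            raise ValueError("confusion matrix needs k >= 2 categories")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_assignments(
        cls, reference: list[int], test: list[int], k: int, first_level: int = 1
    ) -> "ConfusionMatrix":
        ref = np.asarray(reference, int) - first_level
        tst = np.asarray(test, int) - first_level
        if ref.shape != tst.shape:
            raise ValueError("reference and test lengths differ")
        counts = np.zeros((k, k), int)
        np.add.at(counts, (ref, tst), 1)
        return cls(counts=counts)

    def to_csv(self, path: str) -> None:
        labels = self.labels or tuple(str(i + 1) for i in range(self.k))
        pd.DataFrame(self.counts, index=labels, columns=labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str) -> "ConfusionMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(counts=frame.to_numpy(int), labels=tuple(map(str, frame.columns)))


@dataclass
class AgreementResult:
    """Kappa and/or accuracy estimates with standard errors and 95% CIs."""

    n: int
    kappa: float = np.nan
    kappa_se: float = np.nan
    kappa_ci95: tuple[float, float] = (np.nan, np.nan)
    accuracy: float = np.nan
    accuracy_se: float = np.nan
    accuracy_ci95: tuple[float, float] = (np.nan, np.nan)
    undefined: bool = False


@dataclass
class DetectionMetrics:
    lesion_sensitivity: float
    volume_sensitivity: float
    fp_lesions_per_scan: float
    fp_volume_per_scan: float
    n_scans: int
    n_scans_with_reference: int


def _kappa_weights(k: int, weighting: str) -> np.ndarray:
    i, j = np.indices((k, k))
    if weighting == "linear":
        return 1.0 - np.abs(i - j) / (k - 1)
    if weighting == "quadratic":
        return 1.0 - ((i - j) / (k - 1)) ** 2
    raise ValueError(f"weighting must be 'linear' or 'quadratic', got {weighting!r}")


def weighted_kappa(m: ConfusionMatrix, weighting: str = "linear") -> AgreementResult:
    """Weighted Cohen's kappa with its large-sample standard error.

    kappa = (Po_w - Pe_w) / (1 - Pe_w), with agreement weights
    w_ij = 1 - |i - j|/(k - 1) (linear) so that disagreements are penalized
    in proportion to their ordinal distance.  The standard error is the
    large-sample (Fleiss-Cohen-Everitt) form; the 95% CI is the normal
    interval.  When chance agreement is perfect (all mass in one marginal
    cell) kappa is undefined and the result is flagged.
    """
    w = _kappa_weights(m.k, weighting)
    p = m.counts / m.n
    r, c = p.sum(axis=1), p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(r, c)).sum())
    if np.isclose(pe, 1.0):
        return AgreementResult(n=m.n, undefined=True)
    kappa = (po - pe) / (1 - pe)

    wbar_row = w @ c        # expected weight given reference category i
    wbar_col = r @ w        # expected weight given test category j
    cross = wbar_row[:, None] + wbar_col[None, :]
    var = (
        (p * (w * (1 - pe) - cross * (1 - po)) ** 2).sum()
        - (po * pe - 2 * pe + po) ** 2
    ) / (m.n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    zcrit = sps.norm.ppf(0.975)
    return AgreementResult(
        n=m.n,
        kappa=float(kappa),
        kappa_se=se,
        kappa_ci95=(float(kappa - zcrit * se), float(kappa + zcrit * se)),
    )


def accuracy(m: ConfusionMatrix) -> AgreementResult:
    """Proportion of scans on which the two methods agree, with Wilson CI."""
    agree = int(np.trace(m.counts))
    acc = agree / m.n
    lo, hi = proportion_confint(agree, m.n, alpha=0.05, method="wilson")
    se = float(np.sqrt(acc * (1 - acc) / m.n))
    return AgreementResult(
        n=m.n, accuracy=float(acc), accuracy_se=se, accuracy_ci95=(float(lo), float(hi))
    )


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    n_subjects: int
    n_raters: int
    undefined: bool = False


def icc_absolute(scores: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Two-way absolute-agreement intraclass correlation, single measures.

    ``scores`` is an (n subjects x k raters) table without missing cells.
    From the two-way ANOVA decomposition (subjects x raters):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    which, unlike a consistency ICC or a Pearson correlation, penalizes
    systematic offsets between raters.  The confidence interval is the
    standard F-based interval for this form.
    """
    x = np.asarray(scores, float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("scores must be an (n subjects x k>=2 raters) table")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if np.isclose(denom, 0.0):
        return ICCResult(icc=np.nan, ci95=(np.nan, np.nan),
                         n_subjects=n, n_raters=k, undefined=True)
    icc = (msr - mse) / denom

    # F-based CI (two-way absolute agreement, single measures)
    if np.isclose(mse, 0.0) and np.isclose(msc, mse):
        ci = (icc, icc)
    else:
        a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isinf(a) or np.isinf(b):
            ci = (icc, icc)
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr
            )
            ci = (float(lower), float(upper))
    return ICCResult(icc=float(icc), ci95=ci, n_subjects=n, n_raters=k)


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_pairs_used: int
    method: str


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped; tied ranks are averaged.  The exact null
    distribution is used for up to 25 informative pairs, the normal
    approximation with continuity correction above.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero; test undefined")
    method = "exact" if len(d) <= 25 else "approx"
    res = sps.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return WilcoxonResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n_pairs_used=len(d), method=method,
    )


def compare_kappas(r1: AgreementResult, r2: AgreementResult) -> tuple[float, float]:
    """z-test for the difference of two (independent-sample) kappas."""
    if not (np.isfinite(r1.kappa_se) and np.isfinite(r2.kappa_se)):
        raise ValueError("both results must carry kappa standard errors")
    z = (r1.kappa - r2.kappa) / np.hypot(r1.kappa_se, r2.kappa_se)
    return float(z), float(2 * sps.norm.sf(abs(z)))


def compare_accuracies(r1: AgreementResult, r2: AgreementResult) -> tuple[float, float]:
    """Same z-comparison applied to two accuracy estimates."""
    if not (np.isfinite(r1.accuracy_se) and np.isfinite(r2.accuracy_se)):
        raise ValueError("both results must carry accuracy standard errors")
    z = (r1.accuracy - r2.accuracy) / np.hypot(r1.accuracy_se, r2.accuracy_se)
    return float(z), float(2 * sps.norm.sf(abs(z)))


def _voxel_set(lesion: LesionCandidate) -> set[tuple[int, int, int]]:
    return set(map(tuple, lesion.voxel_indices))


def detection_metrics(
    scans: list[tuple[list[LesionCandidate], list[LesionCandidate], float]],
) -> DetectionMetrics:
    """Per-scan detection performance against reference lesions.

    ``scans`` holds one tuple per scan: (reference lesions, detected
    lesions, voxel volume mm^3), with both lesion sets on the same grid.
    A detected lesion is a true positive when it shares at least one voxel
    with any reference lesion; a reference lesion counts as detected when
    any detected lesion overlaps it.  Lesion and volume sensitivity are
    averaged over scans that have reference lesions; false-positive counts
    and volume (total volume of spurious detected lesions) are averaged
    over all scans.
    """
    if not scans:
        raise ValueError("no scans given")
    sens, vol_sens, fp_counts, fp_vols = [], [], [], []
    for reference, detected, voxel_mm3 in scans:
        ref_sets = [_voxel_set(l) for l in reference]
        det_sets = [_voxel_set(l) for l in detected]
        ref_union = set().union(*ref_sets) if ref_sets else set()
        fp = [d for d in det_sets if not (d & ref_union)]
        fp_counts.append(len(fp))
        fp_vols.append(sum(len(d) for d in fp) * voxel_mm3)
        if ref_sets:
            det_union = set().union(*det_sets) if det_sets else set()
            hit = sum(1 for r in ref_sets if r & det_union)
            sens.append(hit / len(ref_sets))
            vol_sens.append(len(ref_union & det_union) / len(ref_union))
    return DetectionMetrics(
        lesion_sensitivity=float(np.mean(sens)) if sens else np.nan,
        volume_sensitivity=float(np.mean(vol_sens)) if vol_sens else np.nan,
        fp_lesions_per_scan=float(np.mean(fp_counts)),
        fp_volume_per_scan=float(np.mean(fp_vols)),
        n_scans=len(scans),
        n_scans_with_reference=len(sens),
    )
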