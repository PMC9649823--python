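"""Agreement statistics between segmentations and volume-measurement methods.

* **DSC** — Dice similarity coefficient ``2TP / (2TP + FP + FN)`` between two
  masks; two empty masks agree vacuously (DSC 1, flagged in reports).
* **Lin's CCC** — concordance correlation coefficient
  ``2*cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)`` with
  population (1/n) moments, penalizing both poor correlation and
  location/scale shift; 95% CI via the Fisher z-transformation with Lin's
  asymptotic variance.
* **ICC(2,1)** — two-way random-effects, absolute-agreement, single-rater
  intraclass correlation from the two-way ANOVA mean squares, with the
  standard F-based confidence interval; the two measurement methods are
  treated as random raters.
* **Mean difference index** — mean over cases of
  ``|ground truth - automated| / ground truth``.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = [
    "dsc",
    "lins_ccc",
    "icc_absolute",
    "mean_difference_index",
    "AgreementReport",
    "agreement_report",
]


def dsc(mask_a, mask_b) -> float:
    """Dice similarity coefficient between two boolean masks.

    Symmetric; 1 iff the masks are identical and non-empty; by convention
    two empty masks also return 1 (perfect vacuous agreement).
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ParameterError(f"mask shapes differ: {a.shape} vs {b.shape}")
    tp = int(np.logical_and(a, b).sum())
    fp = int(np.logical_and(a, ~b).sum())
    fn = int(np.logical_and(~a, b).sum())
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def _as_series(x, y, min_n=3):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ParameterError("series lengths differ")
    if x.size < min_n:
        raise ParameterError(f"need at least {min_n} paired observations")
    return x, y


def lins_ccc(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a Fisher-z 95% CI.

    Uses population (1/n) moments, the original estimator definition. For a
    degenerate perfect concordance (|CCC| numerically 1) the CI collapses to
    the point value.
    """
    x, y = _as_series(x, y)
    n = x.size
    mx, my = x.mean(), y.mean()
    sx2 = float(((x - mx) ** 2).mean())
    sy2 = float(((y - my) ** 2).mean())
    sxy = float(((x - mx) * (y - my)).mean())
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ParameterError("CCC undefined: both series constant and equal")
    ccc = 2.0 * sxy / denom
    if 1.0 - ccc**2 < 1e-12:
        return float(ccc), (float(ccc), float(ccc))
    # Lin (1989, corr. 2000) asymptotic variance of the z-transformed CCC
    r = sxy / np.sqrt(sx2 * sy2) if sx2 > 0 and sy2 > 0 else 0.0
    if r == 0:
        z = np.arctanh(ccc)
        se = 1.0 / np.sqrt(n - 2)
    else:
        u = (mx - my) / (sx2 * sy2) ** 0.25
        se2 = (
            (1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
            + 4 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - ccc**2) ** 2)
            - 2 * ccc**4 * u**4 / (r**2 * (1 - ccc**2) ** 2)
        ) / (n - 2)
        z = np.arctanh(ccc)
        se = float(np.sqrt(max(se2, 0.0)))
    q = stats.norm.ppf(1 - alpha / 2)
    return float(ccc), (float(np.tanh(z - q * se)), float(np.tanh(z + q * se)))


def _two_way_mean_squares(x, y):
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return n, k, msr, msc, mse


def icc_absolute(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Returns the point estimate and the standard F-based confidence interval
    (McGraw & Wong). A degenerate input with the two series identical
    returns 1 with a collapsed (1, 1) interval.
    """
    x, y = _as_series(x, y)
    n, k, msr, msc, mse = _two_way_mean_squares(x, y)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or (mse == 0 and msc == 0):
        if np.array_equal(x, y) and np.var(x) > 0:
            return 1.0, (1.0, 1.0)
        raise ParameterError("ICC undefined for fully degenerate data")
    icc = (msr - mse) / denom
    if mse == 0:
        return float(icc), (float(icc), float(icc))
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return float(icc), (float(icc), float(icc))
    v = (a * msc + b * mse) ** 2 / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), (float(lower), float(upper))


def mean_difference_index(gt, auto) -> float:
    """Mean of |ground-truth - automated| / ground-truth over cases."""
    gt, auto = _as_series(gt, auto, min_n=1)
    if np.any(gt <= 0):
        raise ParameterError("ground-truth volumes must be strictly positive")
    return float(np.mean(np.abs(gt - auto) / gt))


@dataclass(frozen=True)
class AgreementReport:
    """Volume and (optionally) mask agreement between two methods."""

    n: int
    lins_ccc: float
    lins_ccc_ci: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    pearson_r: float
    mean_difference_index: float
    dsc_mean: float | None = None
    dsc_sd: float | None = None
    dsc_all_empty_pairs: int = 0

    def to_dict(self):
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @staticmethod
    def from_json(blob: str) -> "AgreementReport":
        d = json.loads(blob)
        d["lins_ccc_ci"] = tuple(d["lins_ccc_ci"])
        d["icc_ci"] = tuple(d["icc_ci"])
        return AgreementReport(**d)


def agreement_report(gt_volumes, auto_volumes, mask_pairs=None) -> AgreementReport:
    """Assemble the full agreement panel for two volume series.

    ``mask_pairs`` is an optional sequence of (reference, predicted) mask
    pairs; their per-case DSC is summarized as mean +- SD, and vacuously
    perfect (both-empty) pairs are counted in ``dsc_all_empty_pairs``.
    """
    gt, auto = _as_series(gt_volumes, auto_volumes)
    ccc, ccc_ci = lins_ccc(gt, auto)
    icc, icc_ci = icc_absolute(gt, auto)
    r = float(stats.pearsonr(gt, auto).statistic)
    mdi = mean_difference_index(gt, auto)
    dsc_mean = dsc_sd = None
    n_empty = 0
    if mask_pairs is not None:
        scores = []
        for a, b in mask_pairs:
            scores.append(dsc(a, b))
            if not (np.any(a) or np.any(b)):
                n_empty += 1
        dsc_mean = float(np.mean(scores))
        dsc_sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    return AgreementReport(
        n=int(gt.size),
        lins_ccc=ccc,
        lins_ccc_ci=ccc_ci,
        icc=icc,
        icc_ci=icc_ci,
        pearson_r=r,
        mean_difference_index=mdi,
        dsc_mean=dsc_mean,
        dsc_sd=dsc_sd,
        dsc_all_empty_pairs=n_empty,
    )
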