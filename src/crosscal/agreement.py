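"""Continuous-scale agreement between two methods.

Pearson correlation answers "do the methods rank subjects alike?";
Bland-Altman difference analysis and the absolute-agreement intraclass
correlation answer the stricter question "do they give the same numbers?".
Bland-Altman limits can be computed on the natural-log scale when the
differences are skewed, in which case the anti-logged limits are
multiplicative factors (e.g. limits (-0.25, 0.26) mean one method reads
between 0.78 and 1.30 times the other).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DomainError, InsufficientDataError

__all__ = [
    "BlandAltmanResult",
    "ICCResult",
    "pearson_r",
    "bland_altman",
    "icc_absolute_agreement",
]


def _paired_arrays(a, b) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(a, "retained") and b is None:
        a, b = a.retained()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("inputs must be 1-d arrays of equal length")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DomainError("non-finite values in paired input")
    return a, b


def pearson_r(a, b=None) -> float:
    """Product-moment correlation; accepts two arrays or PairedMeasurements."""
    a, b = _paired_arrays(a, b)
    if a.size < 3:
        raise InsufficientDataError("need at least 3 pairs for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DomainError("correlation undefined for a zero-variance column")
    return float(stats.pearsonr(a, b).statistic)


@dataclass
class BlandAltmanResult:
    """Differences-vs-means summary with 1.96-SD limits of agreement."""

    scale: str  # "raw" | "log_e"
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray = field(repr=False)
    differences: np.ndarray = field(repr=False)
    multiplicative_loa: tuple[float, float] | None = None
    multiplicative_mean: float | None = None

    @property
    def se_mean_difference(self) -> float:
        return self.sd_difference / np.sqrt(self.n)


def bland_altman(
    a,
    b=None,
    scale: str = "raw",
    skew_threshold: float = 1.0,
    multiplier: float = 1.96,
) -> BlandAltmanResult:
    """Bland-Altman analysis of paired differences (a - b) vs means.

    ``scale``:
      * ``"raw"``    - differences of the values as given;
      * ``"log_e"``  - differences of natural logs (all values must be > 0);
        the anti-logged mean and limits are reported as multiplicative
        factors;
      * ``"auto"``   - log_e when |Fisher skewness of raw differences| exceeds
        ``skew_threshold``, raw otherwise.

    SD uses the n-1 denominator; limits are mean +/- ``multiplier`` * SD.
    """
    a, b = _paired_arrays(a, b)
    if a.size < 2:
        raise InsufficientDataError("need at least 2 pairs")
    if scale not in ("raw", "log_e", "auto"):
        raise ConfigurationError(f"unknown scale {scale!r}")
    if scale == "auto":
        d_raw = a - b
        sd = d_raw.std(ddof=1)
        skew = stats.skew(d_raw, bias=False) if sd > 0 else 0.0
        scale = "log_e" if abs(skew) > skew_threshold else "raw"
    if scale == "log_e":
        bad = np.where((a <= 0) | (b <= 0))[0]
        if bad.size:
            raise DomainError(
                f"log_e scale requires positive values; offending subjects: "
                f"{bad[:10].tolist()}"
            )
        va, vb = np.log(a), np.log(b)
    else:
        va, vb = a, b
    d = va - vb
    m = (va + vb) / 2.0
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    lo, hi = mean_d - multiplier * sd_d, mean_d + multiplier * sd_d
    result = BlandAltmanResult(
        scale=scale,
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_low=lo,
        loa_high=hi,
        n=d.size,
        means=m,
        differences=d,
    )
    if scale == "log_e":
        result.multiplicative_loa = (float(np.exp(lo)), float(np.exp(hi)))
        result.multiplicative_mean = float(np.exp(mean_d))
    return result


@dataclass
class ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single measures."""

    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_raters: int


def icc_absolute_agreement(matrix) -> ICCResult:
    """Absolute-agreement intraclass correlation from a subjects x methods matrix.

    Two-way ANOVA decomposition (subjects x methods, no replication):

        ICC(A,1) = (MS_R - MS_E) /
                   (MS_R + (k-1) MS_E + (k/n) (MS_C - MS_E))

    The "two-way mixed" and "two-way random" absolute-agreement coefficients
    are numerically identical; the distinction only affects interpretation.
    A constant matrix is defined to have ICC 1 (perfect agreement).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ConfigurationError("expected a 2-d subjects x methods matrix")
    if not np.isfinite(m).all():
        raise DomainError("ICC requires a complete matrix (no missing cells)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need at least 2 subjects and 2 methods")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    resid = m - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid**2).sum()
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    if denom == 0:
        icc = 1.0  # constant matrix: methods agree exactly
    else:
        icc = (ms_rows - ms_err) / denom
    return ICCResult(
        icc=float(icc),
        ms_rows=float(ms_rows),
        ms_cols=float(ms_cols),
        ms_error=float(ms_err),
        n_subjects=n,
        k_raters=k,
    )
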