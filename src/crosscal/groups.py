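"""Z-score standardization and biomarker gradients across ordered risk groups.

Two assays reported in different units can still be compared on how strongly
a biomarker rises across, say, glucose-metabolism categories: standardize
each method's values to Z-scores ((value - population mean) / population SD,
optionally after a natural-log transform for right-skewed analytes), model
the Z-scores on group indicators with covariate adjustment (ANCOVA), and
test a linear trend across the ordered groups.  Whether the gradient itself
differs between the two methods is the group-by-method interaction; for a
two-method repeated design this is exactly the between-group effect on the
within-subject difference of Z-scores.

Z-scores are invariant to any positive affine recalibration of the raw
values, so these comparisons do not require realignment equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError, InsufficientDataError

__all__ = [
    "ZScoreVector",
    "TrendResult",
    "zscore",
    "adjusted_group_means",
    "method_by_group_interaction",
]


@dataclass
class ZScoreVector:
    values: np.ndarray
    mean: float
    sd: float
    log_first: bool = False
    analyte: str = ""
    method: str = ""


def zscore(values, log_first: bool = False, analyte: str = "", method: str = "") -> ZScoreVector:
    """Standardize to mean 0, SD 1 over the analysis population.

    ``log_first`` applies a natural-log transform before standardizing, the
    usual choice for right-skewed acute-phase proteins (CRP, SAA).
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise DomainError("non-finite values cannot be standardized")
    if log_first:
        if (v <= 0).any():
            raise DomainError("log transform requires strictly positive values")
        v = np.log(v)
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        raise DomainError("zero standard deviation: z-scores undefined")
    return ZScoreVector(
        values=(v - mean) / sd,
        mean=mean,
        sd=sd,
        log_first=log_first,
        analyte=analyte,
        method=method,
    )


@dataclass
class TrendResult:
    levels: list[str]
    means: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    trend_estimate: float
    p_trend: float
    p_interaction: float | None = None
    n: int = 0


def _design(groups: pd.Series, levels: list[str], covariates: pd.DataFrame | None):
    """Intercept + treatment-coded group dummies + covariate columns."""
    n = len(groups)
    cols = [np.ones(n)]
    names = ["intercept"]
    codes = pd.Categorical(groups, categories=levels, ordered=True).codes
    if (codes < 0).any():
        raise ConfigurationError("group label outside the declared ordered levels")
    for j, lev in enumerate(levels[1:], start=1):
        cols.append((codes == j).astype(float))
        names.append(f"group[{lev}]")
    if covariates is not None and covariates.shape[1]:
        cov = covariates.to_numpy(dtype=float)
        if not np.isfinite(cov).all():
            raise DomainError("covariates must be complete (no missing values)")
        cols.extend(cov.T)
        names.extend(str(c) for c in covariates.columns)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ConfigurationError(
            f"rank-deficient design ({rank} < {X.shape[1]}); "
            f"check for collinear covariates among {names}"
        )
    return X, names, codes


def _ols(X: np.ndarray, y: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    xtx_inv = np.linalg.pinv(X.T @ X)
    return beta, sigma2, xtx_inv, dof, float(resid @ resid)


def _check_groups(groups: pd.Series, levels: list[str] | None):
    groups = pd.Series(groups)
    if levels is None:
        levels = list(pd.unique(groups))
    counts = groups.value_counts()
    if len(levels) < 2:
        raise ConfigurationError("need at least 2 ordered groups")
    for lev in levels:
        if counts.get(lev, 0) < 2:
            raise InsufficientDataError(f"group {lev!r} has fewer than 2 subjects")
    return groups, levels


def _fit_group_model(
    y: np.ndarray,
    groups: pd.Series,
    levels: list[str],
    covariates: pd.DataFrame | None,
    confidence: float = 0.95,
):
    X, names, codes = _design(groups, levels, covariates)
    beta, sigma2, xtx_inv, dof, ssr = _ols(X, y)
    k = len(levels)
    p_cov = X.shape[1] - k  # covariate columns (excluding intercept/dummies)
    cov_means = X[:, k:].mean(axis=0) if p_cov else np.empty(0)

    # adjusted mean for level j: prediction at that level, covariates at means
    rows = np.zeros((k, X.shape[1]))
    rows[:, 0] = 1.0
    for j in range(1, k):
        rows[j, j] = 1.0
    if p_cov:
        rows[:, k:] = cov_means
    means = rows @ beta
    ses = np.sqrt(np.einsum("ij,jk,ik->i", rows, xtx_inv, rows) * sigma2)
    tq = stats.t.ppf(0.5 + confidence / 2.0, dof) if dof > 0 else 0.0

    # linear trend: centered equally spaced integer scores over the dummies
    scores = np.arange(k, dtype=float)
    scores -= scores.mean()
    contrast = np.zeros(X.shape[1])
    for j in range(1, k):
        contrast[j] = scores[j]
    # intercept coefficient carries score[0] implicitly via sum-to-zero scores:
    # trend = sum_j s_j * mean_j = sum_{j>=1} s_j * beta_j  (covariates cancel)
    est = float(contrast @ beta)
    se = float(np.sqrt(contrast @ xtx_inv @ contrast * sigma2))
    if se == 0:
        p_trend = 1.0 if est == 0 else 0.0
    else:
        p_trend = float(2 * stats.t.sf(abs(est / se), dof))
    return TrendResult(
        levels=list(levels),
        means=means,
        ci_low=means - tq * ses,
        ci_high=means + tq * ses,
        trend_estimate=est,
        p_trend=p_trend,
        n=X.shape[0],
    ), (X, beta, ssr, dof, codes)


def adjusted_group_means(
    z: ZScoreVector | np.ndarray,
    groups,
    covariates: pd.DataFrame | None = None,
    levels: list[str] | None = None,
) -> TrendResult:
    """Covariate-adjusted group means of Z-scores with a linear-trend test.

    ANCOVA: z ~ group indicators + covariates, fitted by least squares.
    Adjusted means are model predictions at the covariate means; the trend
    test contrasts the group means with centered equally spaced scores.
    """
    y = np.asarray(z.values if isinstance(z, ZScoreVector) else z, dtype=float)
    groups, levels = _check_groups(groups, levels)
    if len(y) != len(groups):
        raise ConfigurationError("z and groups must align")
    result, _ = _fit_group_model(y, groups, levels, covariates)
    return result


def method_by_group_interaction(
    z_a: ZScoreVector | np.ndarray,
    z_b: ZScoreVector | np.ndarray,
    groups,
    covariates: pd.DataFrame | None = None,
    levels: list[str] | None = None,
) -> TrendResult:
    """Does the group gradient differ between the two methods?

    For a two-method repeated design the group-by-method interaction is
    exactly the between-group effect on the within-subject difference
    d_i = z_a,i - z_b,i; an F test for the group factor in the covariate-
    adjusted model of d gives p_interaction.  If every d_i is zero the
    methods are identical and p_interaction is 1 by convention.
    """
    a = np.asarray(z_a.values if isinstance(z_a, ZScoreVector) else z_a, dtype=float)
    b = np.asarray(z_b.values if isinstance(z_b, ZScoreVector) else z_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("z_a and z_b must be paired on the same subjects")
    groups, levels = _check_groups(groups, levels)
    if len(a) != len(groups):
        raise ConfigurationError("z-scores and groups must align")
    d = a - b
    if np.allclose(d, 0.0):
        k = len(levels)
        return TrendResult(
            levels=list(levels),
            means=np.zeros(k),
            ci_low=np.zeros(k),
            ci_high=np.zeros(k),
            trend_estimate=0.0,
            p_trend=1.0,
            p_interaction=1.0,
            n=len(d),
        )
    full, (X, beta, ssr_full, dof_full, codes) = _fit_group_model(
        d, groups, levels, covariates
    )
    # reduced model without the group dummies
    k = len(levels)
    keep = [0] + list(range(k, X.shape[1]))
    Xr = X[:, keep]
    _, _, _, dof_r, ssr_r = _ols(Xr, d)
    q = k - 1
    if ssr_full == 0:
        p_int = 1.0 if ssr_r == ssr_full else 0.0
    else:
        f = ((ssr_r - ssr_full) / q) / (ssr_full / dof_full)
        p_int = float(stats.f.sf(f, q, dof_full))
    full.p_interaction = p_int
    return full


def gradient_table(
    frame: pd.DataFrame,
    analyte_columns: dict[str, tuple[str, str]],
    group_column: str,
    levels: list[str],
    covariate_columns: list[str] | None = None,
    log_first: dict[str, bool] | None = None,
    factor_name: str | None = None,
) -> pd.DataFrame:
    """Per analyte x method adjusted Z-score means across ordered groups.

    ``analyte_columns`` maps analyte name -> (method-A column, method-B
    column).  Returns one row per analyte x method x level plus the trend and
    interaction p-values, shaped like a risk-factor gradient table.
    """
    cov = frame[covariate_columns] if covariate_columns else None
    log_first = log_first or {}
    rows = []
    for analyte, (col_a, col_b) in analyte_columns.items():
        logf = log_first.get(analyte, False)
        za = zscore(frame[col_a].to_numpy(), log_first=logf, analyte=analyte, method="A")
        zb = zscore(frame[col_b].to_numpy(), log_first=logf, analyte=analyte, method="B")
        inter = method_by_group_interaction(za, zb, frame[group_column], cov, levels)
        for method, z in (("A", za), ("B", zb)):
            res = adjusted_group_means(z, frame[group_column], cov, levels)
            for j, lev in enumerate(levels):
                rows.append(
                    {
                        "factor": factor_name or group_column,
                        "analyte": analyte,
                        "method": method,
                        "level": lev,
                        "adjusted_mean": res.means[j],
                        "ci_low": res.ci_low[j],
                        "ci_high": res.ci_high[j],
                        "p_trend": res.p_trend,
                        "p_interaction": inter.p_interaction,
                    }
                )
    return pd.DataFrame(rows)
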