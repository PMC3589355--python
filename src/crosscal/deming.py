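"""Errors-in-variables straight-line fitting between two measurement methods.

Deming regression assumes both the predictor and the response are measured
with error.  The closed-form (unweighted) estimator is appropriate when the
error variances are constant over the measuring range; the weighted variant
targets the constant-CV situation common to immunoassays, where the random
error of each method is proportional to the measured concentration.  Weights
are then inversely proportional to the squared estimated true level and the
fit is solved by iterative reweighting (Linnet-style).

Conventions
-----------
``lambda_ratio`` is the ratio of the method-1 (x) to method-2 (y) error
variances at a given true level; for the weighted fit it is the squared
ratio of the two methods' CVs.  The default of 1 corresponds to assuming
equally precise methods (a 1:1 CV ratio).  Confidence intervals are
jackknife (leave-one-out) with a t quantile on n - 2 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateFitError,
    DomainError,
    InsufficientDataError,
)

__all__ = [
    "PairedMeasurements",
    "DemingFit",
    "unweighted_deming_fit",
    "weighted_deming_fit",
    "jackknife_ci",
    "flag_outliers",
]

_POSITIVITY_FLOOR = 1e-12


@dataclass
class PairedMeasurements:
    """Per-subject values of one analyte measured by two methods.

    ``excluded`` flags pairs left out of every computation; ``reasons``
    records why (e.g. ``"outlier"``).
    """

    x: np.ndarray
    y: np.ndarray
    ids: np.ndarray | None = None
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]
    reasons: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ConfigurationError("x and y must be 1-d arrays of equal length")
        n = self.x.size
        if self.ids is None:
            self.ids = np.arange(n)
        else:
            self.ids = np.asarray(self.ids)
        if self.excluded is None:
            self.excluded = np.zeros(n, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.reasons is None:
            self.reasons = np.full(n, "", dtype=object)
        else:
            self.reasons = np.asarray(self.reasons, dtype=object)

    @property
    def n_retained(self) -> int:
        return int((~self.excluded).sum())

    def retained(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.excluded
        return self.x[keep], self.y[keep]

    def exclude(self, mask: np.ndarray, reason: str) -> "PairedMeasurements":
        """Return a copy with additional pairs flagged excluded."""
        mask = np.asarray(mask, dtype=bool)
        excluded = self.excluded | mask
        reasons = self.reasons.copy()
        reasons[mask & ~self.excluded] = reason
        return PairedMeasurements(self.x, self.y, self.ids, excluded, reasons)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        x_col: str,
        y_col: str,
        id_col: str | None = None,
        dropna: bool = True,
    ) -> "PairedMeasurements":
        cols = [x_col, y_col] + ([id_col] if id_col else [])
        sub = frame[cols]
        if dropna:
            sub = sub.dropna()
        ids = sub[id_col].to_numpy() if id_col else None
        return cls(sub[x_col].to_numpy(float), sub[y_col].to_numpy(float), ids)

    @classmethod
    def from_csv(cls, path, x_col: str, y_col: str, id_col: str | None = None):
        return cls.from_dataframe(pd.read_csv(path), x_col, y_col, id_col)


@dataclass
class DemingFit:
    """Result of a (weighted) Deming regression y = intercept + slope * x."""

    intercept: float
    slope: float
    sylx: float
    lambda_ratio: float
    n_pairs: int
    weighted: bool
    n_iterations: int = 0
    converged: bool = True
    intercept_ci: tuple[float, float] | None = None
    slope_ci: tuple[float, float] | None = None
    intercept_se: float | None = None
    slope_se: float | None = None
    weights: np.ndarray | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def summary_row(self, variable: str = "", y: str = "y", x: str = "x") -> dict:
        """One table row per fit: variable, n, intercept (CI), slope (CI), Sylx."""
        row = {
            "variable": variable,
            "n_pairs": self.n_pairs,
            "y": y,
            "x": x,
            "intercept": self.intercept,
            "slope": self.slope,
            "sylx": self.sylx,
        }
        if self.intercept_ci is not None:
            row["intercept_ci_low"], row["intercept_ci_high"] = self.intercept_ci
        if self.slope_ci is not None:
            row["slope_ci_low"], row["slope_ci_high"] = self.slope_ci
        return row


def _check_pairs(pairs: PairedMeasurements, require_positive: bool) -> tuple[np.ndarray, np.ndarray]:
    x, y = pairs.retained()
    if x.size < 3:
        raise InsufficientDataError(
            f"need at least 3 retained pairs, got {x.size}"
        )
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DomainError("non-finite values among retained pairs")
    if require_positive and ((x <= 0).any() or (y <= 0).any()):
        bad = np.where((x <= 0) | (y <= 0))[0]
        raise DomainError(
            f"weighted fitting requires strictly positive values; offending "
            f"retained indices: {bad[:10].tolist()}"
        )
    return x, y


def _moments(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    """Weighted means and central second-moment sums."""
    if w is None:
        w = np.ones_like(x)
    sw = w.sum()
    xbar = float((w * x).sum() / sw)
    ybar = float((w * y).sum() / sw)
    dx = x - xbar
    dy = y - ybar
    sxx = float((w * dx * dx).sum())
    syy = float((w * dy * dy).sum())
    sxy = float((w * dx * dy).sum())
    return xbar, ybar, sxx, syy, sxy


def _deming_line(
    x: np.ndarray, y: np.ndarray, lambda_ratio: float, w: np.ndarray | None = None
) -> tuple[float, float]:
    """Closed-form Deming slope/intercept from (weighted) moment sums.

    With lam = var(x error) / var(y error), substitute delta = 1/lam into the
    standard estimator
        slope = [S_yy - delta*S_xx + sqrt((S_yy - delta*S_xx)^2
                 + 4*delta*S_xy^2)] / (2*S_xy).
    An exact line is recovered for any lam, and lam = 1 gives orthogonal
    regression.
    """
    xbar, ybar, sxx, syy, sxy = _moments(x, y, w)
    if sxx <= 0 or syy <= 0:
        raise DegenerateFitError("all x equal or all y equal: no unique line")
    if sxy == 0:
        raise DegenerateFitError("zero covariance between methods: no linear association")
    delta = 1.0 / lambda_ratio
    disc = (syy - delta * sxx) ** 2 + 4.0 * delta * sxy**2
    slope = (syy - delta * sxx + np.sqrt(disc)) / (2.0 * sxy)
    intercept = ybar - slope * xbar
    return float(intercept), float(slope)


def _residual_sd(
    x: np.ndarray,
    y: np.ndarray,
    intercept: float,
    slope: float,
    w: np.ndarray | None = None,
) -> float:
    r = y - intercept - slope * x
    if w is None:
        w = np.ones_like(r)
    dof = max(x.size - 2, 1)
    return float(np.sqrt((w * r * r).sum() / dof))


def unweighted_deming_fit(
    pairs: PairedMeasurements, lambda_ratio: float = 1.0
) -> DemingFit:
    """Closed-form Deming fit assuming constant error variances.

    Serves both as a stand-alone estimator and as the initializer for the
    iterative weighted fit.
    """
    if lambda_ratio <= 0:
        raise ConfigurationError("lambda_ratio must be positive")
    x, y = _check_pairs(pairs, require_positive=False)
    intercept, slope = _deming_line(x, y, lambda_ratio)
    return DemingFit(
        intercept=intercept,
        slope=slope,
        sylx=_residual_sd(x, y, intercept, slope),
        lambda_ratio=lambda_ratio,
        n_pairs=x.size,
        weighted=False,
    )


def _true_level_projection(
    x: np.ndarray, y: np.ndarray, intercept: float, slope: float, lam: float
) -> np.ndarray:
    """MLE of each pair's true level (x-scale) given the current line.

    Orthogonal projection combining x_i and y_i weighted by the assumed
    error-variance ratio lam = var(x err)/var(y err).
    """
    return (x + lam * slope * (y - intercept)) / (1.0 + lam * slope**2)


def weighted_deming_fit(
    pairs: PairedMeasurements,
    lambda_ratio: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100,
    weight_mode: str = "projection",
) -> DemingFit:
    """Iteratively reweighted Deming fit for proportional (constant-CV) errors.

    Each pair receives weight 1/d_i^2, where d_i is the orthogonal-projection
    estimate of its true level under the current line (``weight_mode
    "projection"``) or the naive mean (x_i + y_i)/2 (``"naive-mean"``, a
    non-iterative cross-check).  Iteration stops when both |d slope| < tol and
    |d intercept| / median(|y|) < tol.
    """
    if lambda_ratio <= 0:
        raise ConfigurationError("lambda_ratio must be positive")
    if weight_mode not in ("projection", "naive-mean"):
        raise ConfigurationError(f"unknown weight_mode {weight_mode!r}")
    x, y = _check_pairs(pairs, require_positive=True)
    yscale = float(np.median(np.abs(y))) or 1.0

    if weight_mode == "naive-mean":
        w = 1.0 / np.maximum((x + y) / 2.0, _POSITIVITY_FLOOR) ** 2
        intercept, slope = _deming_line(x, y, lambda_ratio, w)
        return DemingFit(
            intercept=intercept,
            slope=slope,
            sylx=_residual_sd(x, y, intercept, slope, w),
            lambda_ratio=lambda_ratio,
            n_pairs=x.size,
            weighted=True,
            n_iterations=1,
            converged=True,
            weights=w,
        )

    intercept, slope = _deming_line(x, y, lambda_ratio)
    converged = False
    w = np.ones_like(x)
    n_iter = 0
    # floor on the estimated true level: prevents unbounded weights if a
    # pathological intermediate line sends a projection through zero
    d_floor = max(_POSITIVITY_FLOOR, 1e-3 * float(np.median((x + y) / 2.0)))
    for n_iter in range(1, max_iter + 1):
        d = _true_level_projection(x, y, intercept, slope, lambda_ratio)
        w = 1.0 / np.maximum(np.abs(d), d_floor) ** 2
        new_intercept, new_slope = _deming_line(x, y, lambda_ratio, w)
        if (
            abs(new_slope - slope) < tol
            and abs(new_intercept - intercept) / yscale < tol
        ):
            intercept, slope = new_intercept, new_slope
            converged = True
            break
        intercept, slope = new_intercept, new_slope
    if not converged:
        warnings.warn(
            f"weighted Deming fit did not converge in {max_iter} iterations",
            stacklevel=2,
        )
    return DemingFit(
        intercept=intercept,
        slope=slope,
        sylx=_residual_sd(x, y, intercept, slope, w),
        lambda_ratio=lambda_ratio,
        n_pairs=x.size,
        weighted=True,
        n_iterations=n_iter,
        converged=converged,
        weights=w,
    )


def jackknife_ci(
    pairs: PairedMeasurements,
    fitter: Callable[[PairedMeasurements], DemingFit] | None = None,
    confidence: float = 0.95,
) -> DemingFit:
    """Leave-one-out jackknife confidence intervals for intercept and slope.

    Pseudo-values P_i = n*theta_hat - (n-1)*theta_hat(-i); the CI is
    theta_hat +/- t_{1-(1-confidence)/2, n-2} * SE(pseudo-values).  The result
    does not depend on the ordering of pairs.  Degenerate leave-one-out
    subsets are skipped with a warning.
    """
    if fitter is None:
        fitter = weighted_deming_fit
    keep_idx = np.where(~pairs.excluded)[0]
    n = keep_idx.size
    if n < 4:
        raise InsufficientDataError("jackknife requires at least 4 retained pairs")
    full = fitter(pairs)
    theta = np.array([full.intercept, full.slope])

    loo = np.empty((n, 2))
    ok = np.ones(n, dtype=bool)
    for j, i in enumerate(keep_idx):
        excluded = pairs.excluded.copy()
        excluded[i] = True
        sub = PairedMeasurements(pairs.x, pairs.y, pairs.ids, excluded)
        try:
            f = fitter(sub)
            loo[j] = (f.intercept, f.slope)
        except (DegenerateFitError, DomainError) as exc:  # pragma: no cover - rare
            warnings.warn(f"leave-one-out subset {i} degenerate: {exc}", stacklevel=2)
            ok[j] = False
    loo = loo[ok]
    m = loo.shape[0]
    if m < 3:
        raise InsufficientDataError("too many degenerate leave-one-out subsets")
    pseudo = n * theta - (n - 1) * loo
    se = pseudo.std(axis=0, ddof=1) / np.sqrt(m)
    tq = stats.t.ppf(0.5 + confidence / 2.0, df=n - 2)
    return replace(
        full,
        intercept_ci=(theta[0] - tq * se[0], theta[0] + tq * se[0]),
        slope_ci=(theta[1] - tq * se[1], theta[1] + tq * se[1]),
        intercept_se=float(se[0]),
        slope_se=float(se[1]),
    )


def exclude_below_quantitation(
    pairs: PairedMeasurements, floor: float = 1e-6
) -> PairedMeasurements:
    """Exclude pairs with a reading at or below the quantitation floor.

    Immunoassay readings clipped at (or reported below) the bottom of the
    measuring range are censored, not quantitative; keeping them biases a
    constant-CV weighted fit because they carry large weights at the low end.
    """
    if floor < 0:
        raise ConfigurationError("quantitation floor must be non-negative")
    mask = (pairs.x <= floor) | (pairs.y <= floor)
    if not mask.any():
        return pairs
    return pairs.exclude(mask, "below_quantitation")


def flag_outliers(
    pairs: PairedMeasurements,
    threshold: float = 4.0,
    lambda_ratio: float = 1.0,
    weighted: bool | None = None,
) -> PairedMeasurements:
    """Flag pairs with extreme standardized residuals from a preliminary fit.

    Each retained pair's residual from the preliminary Deming line is scaled
    by its fit weight and compared with a leave-one-out estimate of the
    residual SD, so that a single gross outlier cannot mask itself by
    inflating the scale.  The preliminary fit uses naive-mean weights
    1/((x+y)/2)^2 when all values are positive: unlike the iterative
    projection weights, these do not depend on the fitted line, so a gross
    outlier cannot also capture the preliminary fit.  Pairs beyond
    ``threshold`` are excluded with reason ``"outlier"``; one refit round is
    then performed to catch pairs unmasked by the first exclusion.
    """
    if not np.isfinite(threshold):
        return pairs
    if threshold <= 0:
        raise ConfigurationError("outlier threshold must be positive")

    current = pairs
    for _round in range(2):  # preliminary pass + at most one refit round
        x, y = current.retained()
        if x.size < 4:
            break
        use_weighted = weighted
        if use_weighted is None:
            use_weighted = bool((x > 0).all() and (y > 0).all())
        fit = (
            weighted_deming_fit(current, lambda_ratio, weight_mode="naive-mean")
            if use_weighted
            else unweighted_deming_fit(current, lambda_ratio)
        )
        w = fit.weights if fit.weights is not None else np.ones_like(x)
        u = np.sqrt(w) * (y - fit.predict(x))
        total = float((u * u).sum())
        n = u.size
        # externally studentized: scale for pair i estimated without pair i
        s_loo = np.sqrt(np.maximum(total - u * u, 0.0) / max(n - 3, 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(u) / s_loo
        z[np.abs(u) == 0] = 0.0
        z[(s_loo == 0) & (np.abs(u) > 0)] = np.inf
        flag_retained = z > threshold
        if not flag_retained.any():
            break
        mask = np.zeros(current.x.size, dtype=bool)
        mask[np.where(~current.excluded)[0][flag_retained]] = True
        current = current.exclude(mask, "outlier")
    return current


def fits_to_frame(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble per-fit summary rows into a regression summary table."""
    return pd.DataFrame(rows)
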