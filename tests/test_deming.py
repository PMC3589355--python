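"""Deming regression: closed form, iterative reweighting, jackknife, outliers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crosscal.deming import (
    DemingFit,
    PairedMeasurements,
    exclude_below_quantitation,
    flag_outliers,
    jackknife_ci,
    unweighted_deming_fit,
    weighted_deming_fit,
)
from crosscal.errors import (
    ConfigurationError,
    DegenerateFitError,
    DomainError,
    InsufficientDataError,
)


def pairs_of(x, y):
    return PairedMeasurements(np.asarray(x, float), np.asarray(y, float))


class TestUnweighted:
    @pytest.mark.parametrize(
        "x, y, slope, intercept",
        [
            ([1, 2, 3], [1, 2, 3], 1.0, 0.0),  # identity line
            ([1, 2, 3], [3, 5, 7], 2.0, 1.0),  # exact y = 2x + 1
            # hand-evaluated closed form: S_xx=2, S_yy=14/3, S_xy=3
            ([1, 2, 3], [2, 3, 5], 1.5387619779773447, 0.25580937737864407),
        ],
    )
    def test_known_lines(self, x, y, slope, intercept):
        fit = unweighted_deming_fit(pairs_of(x, y), lambda_ratio=1.0)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    @pytest.mark.parametrize("lam", [0.1, 1.0, 7.5])
    def test_exact_line_recovered_for_any_lambda(self, lam):
        x = np.linspace(1, 9, 12)
        fit = unweighted_deming_fit(pairs_of(x, 2 * x + 1), lambda_ratio=lam)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.sylx == pytest.approx(0.0, abs=1e-10)

    def test_zero_covariance_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            unweighted_deming_fit(pairs_of([1, 2, 1, 2], [1, 1, 2, 2]))

    def test_constant_column_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            unweighted_deming_fit(pairs_of([2, 2, 2], [1, 2, 3]))

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            unweighted_deming_fit(pairs_of([1, 2], [1, 2]))

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ConfigurationError):
            unweighted_deming_fit(pairs_of([1, 2, 3], [2, 3, 5]), lambda_ratio=0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        c=st.floats(0.01, 100),
        seed=st.integers(0, 10_000),
    )
    def test_scale_equivariance(self, c, seed):
        """Rescaling both axes by c leaves the slope, scales the intercept."""
        r = np.random.default_rng(seed)
        x = r.uniform(1, 10, 15)
        y = 0.5 + 1.3 * x + r.normal(0, 0.3, 15)
        f1 = unweighted_deming_fit(pairs_of(x, y))
        f2 = unweighted_deming_fit(pairs_of(c * x, c * y))
        assert f2.slope == pytest.approx(f1.slope, rel=1e-9)
        assert f2.intercept == pytest.approx(c * f1.intercept, rel=1e-7, abs=1e-9)


class TestWeighted:
    def test_noiseless_calibration_line_recovered_fast(self):
        # generating line of the CRP cross-calibration, zero noise
        x = np.array([0.5, 1, 2, 4, 8, 16], float)
        fit = weighted_deming_fit(pairs_of(x, -0.33 + 0.93 * x))
        assert fit.slope == pytest.approx(0.93, abs=1e-10)
        assert fit.intercept == pytest.approx(-0.33, abs=1e-10)
        assert fit.converged and fit.n_iterations <= 3

    def test_identity_data_unbroken_by_weighting(self):
        x = np.geomspace(0.2, 50, 20)
        fit = weighted_deming_fit(pairs_of(x, x))
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(DomainError):
            weighted_deming_fit(pairs_of([1, 2, -3], [1, 2, 3]))

    def test_naive_mean_weight_mode_close_to_iterative(self, rng):
        x = rng.lognormal(1, 0.8, 80)
        y = (0.5 + 0.8 * x) * (1 + 0.05 * rng.standard_normal(80))
        f1 = weighted_deming_fit(pairs_of(x, y))
        f2 = weighted_deming_fit(pairs_of(x, y), weight_mode="naive-mean")
        assert f2.slope == pytest.approx(f1.slope, rel=0.05)

    def test_symmetry_inversion_at_unit_lambda(self, rng):
        """Fitting y-on-x and x-on-y yields mutually inverse lines.

        Exact for the unweighted orthogonal fit; the weighted variant agrees
        only approximately because the two directions weight by estimated
        true levels on different scales.
        """
        x = rng.lognormal(1, 0.7, 120)
        y = (0.4 + 0.9 * x) * (1 + 0.03 * rng.standard_normal(120))
        u_yx = unweighted_deming_fit(pairs_of(x, y))
        u_xy = unweighted_deming_fit(pairs_of(y, x))
        assert u_xy.slope == pytest.approx(1 / u_yx.slope, rel=1e-10)
        assert u_xy.intercept == pytest.approx(
            -u_yx.intercept / u_yx.slope, rel=1e-9
        )
        f_yx = weighted_deming_fit(pairs_of(x, y))
        f_xy = weighted_deming_fit(pairs_of(y, x))
        assert f_xy.slope == pytest.approx(1 / f_yx.slope, rel=1e-2)
        assert f_xy.intercept == pytest.approx(-f_yx.intercept / f_yx.slope, rel=0.05)

    def test_objective_not_beaten_on_grid(self, rng):
        """Weighted orthogonal SSQ with converged weights frozen is minimal."""
        x = rng.lognormal(0.5, 0.6, 20)
        y = (0.3 + 1.2 * x) * (1 + 0.08 * rng.standard_normal(20))
        fit = weighted_deming_fit(pairs_of(x, y))
        w = fit.weights
        lam = fit.lambda_ratio

        def objective(a, b):
            # weighted sum of squared orthogonal distances at lambda = 1
            return float(np.sum(w * (y - a - b * x) ** 2 / (1 + lam * b**2)))

        best = objective(fit.intercept, fit.slope)
        for da in np.linspace(-0.05, 0.05, 21):
            for db in np.linspace(-0.05, 0.05, 21):
                assert objective(fit.intercept + da, fit.slope + db) >= best - 1e-12


class TestJackknife:
    def test_exact_line_gives_zero_width_ci(self):
        x = np.linspace(1, 5, 8)
        fit = jackknife_ci(pairs_of(x, 2 * x + 1))
        lo, hi = fit.slope_ci
        assert hi - lo == pytest.approx(0.0, abs=1e-9)
        lo, hi = fit.intercept_ci
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_order_invariance(self, rng):
        x = rng.lognormal(1, 0.5, 40)
        y = (0.2 + 1.1 * x) * (1 + 0.05 * rng.standard_normal(40))
        perm = rng.permutation(40)
        f1 = jackknife_ci(pairs_of(x, y))
        f2 = jackknife_ci(pairs_of(x[perm], y[perm]))
        assert f1.slope_ci == pytest.approx(f2.slope_ci, rel=1e-10)
        assert f1.intercept_ci == pytest.approx(f2.intercept_ci, rel=1e-10)

    def test_ci_brackets_point_estimate(self, rng):
        x = rng.lognormal(1, 0.5, 25)
        y = (0.2 + 1.1 * x) * (1 + 0.05 * rng.standard_normal(25))
        fit = jackknife_ci(pairs_of(x, y))
        assert fit.intercept_ci[0] <= fit.intercept <= fit.intercept_ci[1]
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]

    def test_minimum_pairs(self):
        with pytest.raises(InsufficientDataError):
            jackknife_ci(pairs_of([1, 2, 3], [2, 3, 5]))


class TestOutliers:
    def test_clean_line_flags_nothing(self):
        x = np.linspace(1, 10, 15)
        out = flag_outliers(pairs_of(x, x), threshold=4.0)
        assert not out.excluded.any()

    def test_single_gross_outlier_flagged(self):
        x = np.concatenate([np.arange(1, 21.0), [1.0]])
        y = x.copy()
        y[-1] = 100.0
        out = flag_outliers(pairs_of(x, y), threshold=4.0)
        assert list(np.where(out.excluded)[0]) == [20]
        assert out.reasons[20] == "outlier"

    def test_infinite_threshold_is_noop(self):
        x = np.concatenate([np.arange(1, 21.0), [1.0]])
        y = x.copy()
        y[-1] = 100.0
        out = flag_outliers(pairs_of(x, y), threshold=np.inf)
        assert not out.excluded.any()

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            flag_outliers(pairs_of([1, 2, 3, 4], [1, 2, 3, 4]), threshold=0)

    def test_censored_readings_excluded(self):
        x = np.array([0.3, 1.0, 2.0, 4.0])
        y = np.array([1e-6, 0.6, 1.5, 3.4])
        out = exclude_below_quantitation(pairs_of(x, y))
        assert list(np.where(out.excluded)[0]) == [0]
        assert out.reasons[0] == "below_quantitation"


class TestPairedMeasurements:
    def test_exclusions_removed_from_fit(self):
        p = pairs_of([1, 2, 3, 50], [1, 2, 3, 1]).exclude(
            np.array([False, False, False, True]), "manual"
        )
        assert p.n_retained == 3
        fit = unweighted_deming_fit(p)
        assert fit.slope == pytest.approx(1.0)
        assert fit.n_pairs == 3

    def test_summary_row_layout(self):
        fit = unweighted_deming_fit(pairs_of([1, 2, 3], [2, 3, 5]))
        row = fit.summary_row("CRP", y="multiplex", x="single")
        assert row["variable"] == "CRP" and row["n_pairs"] == 3
        assert {"intercept", "slope", "sylx"} <= set(row)
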