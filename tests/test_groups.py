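"""Z-scores, adjusted group means/trends, method-by-group interaction."""

import numpy as np
import pandas as pd
import pytest

from crosscal.errors import ConfigurationError, DomainError
from crosscal.groups import (
    adjusted_group_means,
    gradient_table,
    method_by_group_interaction,
    zscore,
)

LEVELS = ["g1", "g2", "g3"]


def make_groups(n_per, rng=None):
    return pd.Series(np.repeat(LEVELS, n_per))


class TestZScore:
    def test_simple_example(self):
        z = zscore([1.0, 2.0, 3.0])
        assert z.values == pytest.approx([-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self, rng):
        z = zscore(rng.lognormal(2, 1, 500))
        assert z.values.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.values.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_log_first(self):
        z = zscore(np.exp([1.0, 2.0, 3.0]), log_first=True)
        assert z.values == pytest.approx([-1.0, 0.0, 1.0])

    def test_log_first_requires_positive(self):
        with pytest.raises(DomainError):
            zscore([1.0, -1.0], log_first=True)

    def test_zero_sd_rejected(self):
        with pytest.raises(DomainError):
            zscore([2.0, 2.0, 2.0])

    def test_invariant_to_positive_affine_recalibration(self, rng):
        v = rng.lognormal(1, 0.6, 100)
        z1 = zscore(v)
        z2 = zscore(0.47 + 0.14 * v)
        assert z2.values == pytest.approx(z1.values, abs=1e-10)


class TestAdjustedMeans:
    def test_equal_groups_no_trend(self, rng):
        y = np.tile([1.0, -1.0, 0.5, -0.5], 6)  # identical within each group
        groups = pd.Series(np.repeat(LEVELS, 8))
        res = adjusted_group_means(y, groups, levels=LEVELS)
        assert res.trend_estimate == pytest.approx(0.0, abs=1e-12)
        assert res.p_trend > 0.99

    def test_cis_bracket_means(self, rng):
        y = rng.standard_normal(60)
        res = adjusted_group_means(y, make_groups(20), levels=LEVELS)
        assert (res.ci_low <= res.means).all() and (res.means <= res.ci_high).all()

    def test_trend_detected_with_power(self):
        """Shifts (-0.3, 0, +0.3) at n=180/group: p_trend < 0.001 nearly always."""
        hits = 0
        reps = 100
        shifts = {"g1": -0.3, "g2": 0.0, "g3": 0.3}
        groups = make_groups(180)
        offset = groups.map(shifts).to_numpy()
        for r in range(reps):
            rng = np.random.default_rng(900 + r)
            y = offset + rng.standard_normal(540)
            res = adjusted_group_means(y, groups, levels=LEVELS)
            hits += res.p_trend < 0.001
        assert hits >= 0.95 * reps

    def test_irrelevant_covariate_barely_moves_means(self, rng):
        y = np.repeat([0.0, 0.2, 0.4], 100) + rng.standard_normal(300)
        groups = make_groups(100)
        noise_cov = pd.DataFrame({"junk": rng.standard_normal(300)})
        bare = adjusted_group_means(y, groups, levels=LEVELS)
        adj = adjusted_group_means(y, groups, covariates=noise_cov, levels=LEVELS)
        mc_se = 1 / np.sqrt(100)
        assert np.abs(adj.means - bare.means).max() < 2 * mc_se

    def test_trend_sign_flips_with_group_order(self, rng):
        y = np.repeat([0.0, 0.3, 0.6], 50) + 0.1 * rng.standard_normal(150)
        groups = make_groups(50)
        fwd = adjusted_group_means(y, groups, levels=LEVELS)
        rev = adjusted_group_means(y, groups, levels=LEVELS[::-1])
        assert rev.trend_estimate == pytest.approx(-fwd.trend_estimate, rel=1e-9)
        assert rev.p_trend == pytest.approx(fwd.p_trend, rel=1e-6)

    def test_collinear_covariates_rejected(self, rng):
        y = rng.standard_normal(30)
        cov = pd.DataFrame({"a": np.arange(30.0), "b": 2 * np.arange(30.0)})
        with pytest.raises(ConfigurationError, match="rank"):
            adjusted_group_means(y, make_groups(10), covariates=cov, levels=LEVELS)


class TestInteraction:
    def test_identical_methods_give_p_one(self, rng):
        z = rng.standard_normal(30)
        res = method_by_group_interaction(z, z.copy(), make_groups(10), levels=LEVELS)
        assert res.p_interaction == 1.0

    def test_matches_mixed_anova_oracle(self):
        """Difference-regression F equals the split-plot interaction F."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        n = 18
        groups = np.repeat(LEVELS, 6)
        t = rng.normal(size=n)
        za = t + rng.normal(scale=0.5, size=n)
        zb = t + rng.normal(scale=0.5, size=n)
        zb[groups == "g3"] += 0.8
        mine = method_by_group_interaction(za, zb, pd.Series(groups), levels=LEVELS)
        long = pd.DataFrame(
            {
                "y": np.concatenate([za, zb]),
                "method": ["A"] * n + ["B"] * n,
                "subject": list(range(n)) * 2,
                "group": list(groups) * 2,
            }
        )
        oracle = pingouin.mixed_anova(
            long, dv="y", within="method", subject="subject", between="group"
        )
        p_oracle = float(oracle.loc[oracle["Source"] == "Interaction", "p_unc"].iloc[0])
        assert mine.p_interaction == pytest.approx(p_oracle, abs=1e-10)

    def test_within_group_permutation_degenerates_to_p_one(self, rng):
        """Permuting values within groups preserves group sums, so the
        between-group signal in the differences is exactly zero."""
        groups = make_groups(12)
        za = rng.standard_normal(36)
        zb = za.copy()
        for g in LEVELS:
            idx = np.where(groups == g)[0]
            zb[idx] = za[rng.permutation(idx)]
        res = method_by_group_interaction(za, zb, groups, levels=LEVELS)
        assert res.p_interaction > 0.99

    def test_method_specific_effect_detected(self):
        """+0.3 z in one method's top group only, n=180/group: high power."""
        hits = 0
        reps = 60
        groups = make_groups(180)
        top = (groups == "g3").to_numpy()
        for r in range(reps):
            rng = np.random.default_rng(4200 + r)
            t = rng.standard_normal(540)
            za = t + 0.3 * rng.standard_normal(540)
            zb = t + 0.3 * rng.standard_normal(540)
            za[top] += 0.3
            res = method_by_group_interaction(za, zb, groups, levels=LEVELS)
            hits += res.p_interaction < 0.05
        assert hits >= 0.8 * reps

    def test_unpaired_inputs_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            method_by_group_interaction(
                rng.standard_normal(10), rng.standard_normal(9), make_groups(3)
            )


def test_gradient_table_shape(default_cohort):
    frame = default_cohort.data
    table = gradient_table(
        frame,
        {"CRP": ("CRP_methodA", "CRP_methodB")},
        "glucose_metabolism",
        ["NGM", "IGM", "DM2"],
        covariate_columns=["age", "female", "egfr", "prior_cvd"],
        log_first={"CRP": True},
    )
    assert len(table) == 6  # 2 methods x 3 levels
    assert set(table.columns) >= {
        "analyte",
        "method",
        "level",
        "adjusted_mean",
        "p_trend",
        "p_interaction",
    }
    # the configured gradient rises across glucose-metabolism categories
    means_a = table[table.method == "A"].set_index("level")["adjusted_mean"]
    assert means_a["NGM"] < means_a["DM2"]
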