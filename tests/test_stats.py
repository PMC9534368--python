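"""χ², gender-adjusted ANOVA with ω², Scheffé / Fisher LSD, Spearman CI."""

import numpy as np
import pytest
from scipy import stats as sps

from cpmpheno.stats import (
    ContingencyTable,
    EffectMagnitude,
    anova_gender_controlled,
    fisher_lsd_pairwise,
    omega_squared_magnitude,
    pearson_chi2,
    scheffe_pairwise,
    spearman_ci,
)


def brute_force_chi2(counts):
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            e = counts[i].sum() * counts[:, j].sum() / total
            stat += (counts[i, j] - e) ** 2 / e
    return stat


def _table(counts, prefix="r"):
    counts = np.asarray(counts)
    return ContingencyTable(
        [f"{prefix}{i}" for i in range(counts.shape[0])],
        [f"c{j}" for j in range(counts.shape[1])],
        counts,
    )


class TestPearsonChi2:
    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 60, size=(3, 3))
            stat, df, p = pearson_chi2(_table(counts))
            assert stat == pytest.approx(brute_force_chi2(counts), abs=1e-10)
            assert df == 4

    def test_proportional_rows_give_zero(self):
        stat, _, p = pearson_chi2(_table([[10, 20, 30], [20, 40, 60]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariance_under_permutation_and_transpose(self, rng):
        counts = rng.integers(1, 40, size=(3, 4))
        base, _, _ = pearson_chi2(_table(counts))
        perm, _, _ = pearson_chi2(_table(counts[[2, 0, 1]][:, [3, 1, 0, 2]]))
        tr, _, _ = pearson_chi2(_table(counts.T))
        assert base == pytest.approx(perm, abs=1e-10)
        assert base == pytest.approx(tr, abs=1e-10)

    def test_zero_marginal_identified(self):
        with pytest.raises(ValueError, match="r1"):
            pearson_chi2(_table([[5, 5], [0, 0]]))

    def test_small_tables_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2(ContingencyTable(["a"], ["x", "y"], np.array([[1, 2]])))


def _balanced_fixture(rng, n_per=20, shift=(0.0, 0.0, 0.0)):
    values, groups, genders = [], [], []
    for gi, s in enumerate(shift):
        for sex in ("F", "M"):
            values.extend(rng.normal(s, 1.0, n_per))
            groups.extend([f"g{gi}"] * n_per)
            genders.extend([sex] * n_per)
    return np.array(values), np.array(groups), np.array(genders)


def classical_oneway_F(values, groups):
    labels = sorted(set(groups))
    ybar = values.mean()
    ss_b = sum(
        (groups == g).sum() * (values[groups == g].mean() - ybar) ** 2 for g in labels
    )
    ss_w = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum() for g in labels)
    df_b, df_w = len(labels) - 1, len(values) - len(labels)
    return (ss_b / df_b) / (ss_w / df_w)


class TestGenderControlledAnova:
    def test_null_effect_small_F_nonpositive_omega(self, rng):
        values, groups, genders = _balanced_fixture(rng, n_per=200)
        res = anova_gender_controlled(values, groups, genders)
        assert res.F_group < 3.0
        assert res.omega_sq < 0.01
        assert res.magnitude is EffectMagnitude.NEGLIGIBLE

    def test_balanced_no_gender_effect_equals_classical_oneway(self, rng):
        """With genders balanced within groups and no gender effect in the
        generating model, the Type II group F equals the classical one-way F
        computed with gender pooled into error... up to the error df; here we
        verify against the explicit nested-model (extra sum of squares)
        computation, which is exact."""
        values, groups, genders = _balanced_fixture(rng, shift=(0.0, 0.5, 1.0))
        res = anova_gender_controlled(values, groups, genders)
        F = _nested_model_F(values, groups, genders)
        assert res.F_group == pytest.approx(F, abs=1e-8)

    def test_unbalanced_three_groups_match_nested_models(self, rng):
        values, groups, genders = [], [], []
        sizes = {"g0": 25, "g1": 40, "g2": 13}
        for gi, (g, n) in enumerate(sizes.items()):
            values.extend(rng.normal(gi * 0.7, 1.0, n))
            groups.extend([g] * n)
            genders.extend(rng.choice(["F", "M"], size=n, p=[0.7, 0.3]))
        values, groups, genders = map(np.array, (values, groups, genders))
        res = anova_gender_controlled(values, groups, genders)
        assert res.F_group == pytest.approx(_nested_model_F(values, groups, genders), abs=1e-8)

    def test_omega_not_above_eta_squared(self, rng):
        for _ in range(10):
            values, groups, genders = _balanced_fixture(
                rng, n_per=15, shift=tuple(rng.normal(0, 1, 3))
            )
            res = anova_gender_controlled(values, groups, genders)
            ss_total = ((values - values.mean()) ** 2).sum()
            labels = sorted(set(groups))
            ybar = values.mean()
            ss_group = sum(
                (groups == g).sum() * (values[groups == g].mean() - ybar) ** 2
                for g in labels
            )
            eta = ss_group / ss_total
            assert res.omega_sq <= eta + 1e-12

    def test_confounded_design_rejected(self):
        values = np.arange(10.0)
        groups = np.array(["a"] * 5 + ["b"] * 5)
        genders = np.array(["F"] * 5 + ["M"] * 5)
        with pytest.raises(ValueError, match="confound"):
            anova_gender_controlled(values, groups, genders)

    @pytest.mark.parametrize(
        "omega,expected",
        [(-0.02, EffectMagnitude.NEGLIGIBLE), (0.01, EffectMagnitude.SMALL),
         (0.06, EffectMagnitude.MEDIUM), (0.2, EffectMagnitude.LARGE)],
    )
    def test_magnitude_thresholds(self, omega, expected):
        assert omega_squared_magnitude(omega) is expected


def _nested_model_F(values, groups, genders):
    """Type II F for the group factor by explicit nested-model comparison."""

    def rss(design):
        beta, *_ = np.linalg.lstsq(design, values, rcond=None)
        resid = values - design @ beta
        return (resid**2).sum()

    glabels = sorted(set(groups))
    g_dummies = np.column_stack([(groups == g).astype(float) for g in glabels[1:]])
    sex_dummy = (genders == sorted(set(genders))[1]).astype(float)[:, None]
    ones = np.ones((len(values), 1))
    rss_full = rss(np.hstack([ones, g_dummies, sex_dummy]))
    rss_reduced = rss(np.hstack([ones, sex_dummy]))
    df_group = len(glabels) - 1
    df_error = len(values) - (1 + df_group + 1)
    return ((rss_reduced - rss_full) / df_group) / (rss_full / df_error)


class TestPosthoc:
    def test_identical_groups_p_one(self, rng):
        base = rng.normal(size=30)
        values = np.concatenate([base, base, rng.normal(2, 1, 30)])
        groups = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        genders = np.tile(["F", "M"], 45)
        sch = scheffe_pairwise(values, groups, genders)
        lsd = fisher_lsd_pairwise(values, groups)
        assert sch.p("a", "b") == pytest.approx(1.0)
        assert lsd.p("a", "b") == pytest.approx(1.0)

    def test_two_group_lsd_equals_pooled_t(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.8, 1, 31)
        values = np.concatenate([x, y])
        groups = np.array(["a"] * 25 + ["b"] * 31)
        lsd = fisher_lsd_pairwise(values, groups)
        _, p = sps.ttest_ind(x, y, equal_var=True)
        assert lsd.p("a", "b") == pytest.approx(p, abs=1e-10)

    def test_scheffe_at_least_as_conservative_as_lsd(self, rng):
        violations = 0
        for _ in range(100):
            values, groups, genders = _balanced_fixture(
                rng, n_per=12, shift=tuple(rng.normal(0, 0.8, 3))
            )
            sch = scheffe_pairwise(values, groups, genders)
            lsd = fisher_lsd_pairwise(values, groups)
            for c in lsd.comparisons:
                if sch.p(c.group_a, c.group_b) < c.p_value - 1e-9:
                    violations += 1
        assert violations == 0

    def test_scheffe_p_monotone_in_mean_difference(self, rng):
        genders = np.tile(["F", "M"], 45)
        groups = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        noise = rng.normal(0, 1, 90)
        ps = []
        for shift in (0.2, 0.6, 1.2, 2.4):
            values = noise + np.where(groups == "b", shift, 0.0)
            ps.append(scheffe_pairwise(values, groups, genders).p("a", "b"))
        assert ps == sorted(ps, reverse=True)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            fisher_lsd_pairwise(np.arange(5.0), np.array(["a"] * 4 + ["b"]))


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        res = spearman_ci(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)
        res = spearman_ci(x, -x)
        assert res.rho == pytest.approx(-1.0)

    def test_ci_brackets_rho_and_stays_in_range(self, rng):
        for _ in range(10):
            x = rng.normal(size=50)
            y = 0.3 * x + rng.normal(size=50)
            res = spearman_ci(x, y)
            lo, hi = res.ci95
            assert -1.0 <= lo <= res.rho <= hi <= 1.0
            assert 0.0 <= res.p_value <= 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_ci(np.ones(10), np.arange(10.0))

    def test_reported_ci_width_at_large_n(self, rng):
        """At n ≈ 600 and a weak rank correlation the Fieller-type interval
        spans roughly 0.15, the width the method is expected to give."""
        x = rng.normal(size=600)
        y = 0.145 * x + rng.normal(size=600) * np.sqrt(1 - 0.145**2)
        res = spearman_ci(x, y)
        width = res.ci95[1] - res.ci95[0]
        assert 0.12 < width < 0.19
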