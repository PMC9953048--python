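import math

import numpy as np
import pandas as pd
import pytest

from grimkit.stats import (
    DegenerateSampleError,
    dunnett_rm_pvalues,
    icc,
    one_way_anova,
    pearson_control,
    response_profile,
    rm_anova_dunnett,
    sidak_adjust,
    two_way_anova,
    welch_t,
)


def changes_table(values_by_condition, parameter="eye_opening"):
    rows = []
    for condition, values in values_by_condition.items():
        for i, v in enumerate(values):
            rows.append({
                "animal_id": f"a{i}", "condition": condition, parameter: v,
            })
    return pd.DataFrame(rows)


class TestResponseProfile:
    def test_symmetric_sample_gives_t_zero(self):
        df = changes_table({"water": [-0.1, 0.1, -0.3, 0.3]})
        r = response_profile(df, "water", m=1)["eye_opening"]
        assert r.t == pytest.approx(0.0, abs=1e-12)
        assert r.p_raw == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_t_formula(self, rng):
        values = 0.2 + rng.normal(0, 0.05, size=10)
        df = changes_table({"sucrose": values})
        r = response_profile(df, "sucrose", m=1)["eye_opening"]
        expected_t = values.mean() / (values.std(ddof=1) / math.sqrt(len(values)))
        assert r.t == pytest.approx(expected_t, abs=1e-9)
        assert r.t > 0 and np.sign(r.t) == np.sign(values.mean())
        assert r.p_adj < 0.05

    def test_bonferroni_arithmetic(self):
        df = changes_table({"water": [0.1, 0.2, 0.15, 0.22, 0.18]})
        r = response_profile(df, "water", m=3)["eye_opening"]
        assert r.p_adj == pytest.approx(min(1.0, 3 * r.p_raw), abs=1e-12)
        assert r.p_adj >= r.p_raw

    def test_zero_variance_errors(self):
        df = changes_table({"water": [0.2, 0.2, 0.2]})
        with pytest.raises(DegenerateSampleError):
            response_profile(df, "water", m=1)


class TestOneWayAnova:
    def test_identical_groups_f_zero(self):
        df = changes_table({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}).rename(
            columns={"condition": "group"})
        result, _ = one_way_anova(df, "eye_opening", "group")
        assert result.F == pytest.approx(0.0, abs=1e-12)

    def test_matches_manual_sums_of_squares(self, rng):
        groups = {g: rng.normal(mu, 1.0, size=5).tolist()
                  for g, mu in (("a", 0.0), ("b", 0.5), ("c", 1.0))}
        df = changes_table(groups)
        result, posthoc = one_way_anova(df, "eye_opening", "condition")
        # independent oracle: explicit between/within decomposition
        allv = np.concatenate([np.array(v) for v in groups.values()])
        grand = allv.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f_oracle = (ss_between / 2) / (ss_within / (len(allv) - 3))
        assert result.F == pytest.approx(f_oracle, rel=1e-9)
        assert result.df1 == 2 and result.df2 == 12
        assert len(posthoc.pairs) == 3
        assert all(0 <= p <= 1 for p in posthoc.p_adj)

    def test_two_groups_tukey_equals_pooled_t(self, rng):
        groups = {"a": rng.normal(0, 1, 8).tolist(), "b": rng.normal(1, 1, 8).tolist()}
        df = changes_table(groups)
        _, posthoc = one_way_anova(df, "eye_opening", "condition")
        from scipy import stats as sps
        t_p = sps.ttest_ind(groups["a"], groups["b"], equal_var=True).pvalue
        assert posthoc.p_adj[0] == pytest.approx(t_p, abs=1e-6)

    def test_small_group_errors(self):
        df = changes_table({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="< 2"):
            one_way_anova(df, "eye_opening", "condition")

    def test_f_invariant_to_shift_and_scale(self, rng):
        groups = {g: rng.normal(m, 1, 6).tolist() for g, m in (("a", 0), ("b", 1))}
        df = changes_table(groups)
        base, _ = one_way_anova(df, "eye_opening", "condition")
        df2 = df.assign(eye_opening=3.0 * df.eye_opening + 11.0)
        shifted, _ = one_way_anova(df2, "eye_opening", "condition")
        assert shifted.F == pytest.approx(base.F, rel=1e-9)
        assert shifted.p == pytest.approx(base.p, rel=1e-9)


def balanced_mixed_design(rng, interaction=0.0, n_per_group=8):
    rows = []
    for g in ("wt", "het"):
        for s in range(n_per_group):
            subj = f"{g}{s}"
            subj_effect = rng.normal(0, 0.2)
            for level, shift in (("pre", 0.0), ("stim", 0.4), ("post", 0.1)):
                bump = interaction if (g == "het" and level == "stim") else 0.0
                rows.append({
                    "animal_id": subj, "genotype": g, "stimulus": level,
                    "v": subj_effect + shift + bump + rng.normal(0, 0.2),
                })
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_between_design_matches_manual_balanced_oracle(self, rng):
        rows = []
        means = {("n", "x"): 0.0, ("n", "y"): 0.5, ("n", "z"): 0.2,
                 ("h", "x"): 0.1, ("h", "y"): 0.9, ("h", "z"): 0.4}
        for (a, b), mu in means.items():
            for i in range(5):
                rows.append({"animal_id": f"{a}{b}{i}", "fa": a, "fb": b,
                             "v": mu + rng.normal(0, 0.3)})
        df = pd.DataFrame(rows)
        effects, _ = two_way_anova(df, "v", "fa", "fb")
        # manual balanced two-way decomposition
        grand = df.v.mean()
        na = df.fa.nunique()
        nb = df.fb.nunique()
        r = 5
        ss_a = nb * r * sum((df[df.fa == a].v.mean() - grand) ** 2 for a in df.fa.unique())
        ss_b = na * r * sum((df[df.fb == b].v.mean() - grand) ** 2 for b in df.fb.unique())
        ss_cells = r * sum(
            (df[(df.fa == a) & (df.fb == b)].v.mean() - grand) ** 2
            for a in df.fa.unique() for b in df.fb.unique())
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(
            ((df[(df.fa == a) & (df.fb == b)].v
              - df[(df.fa == a) & (df.fb == b)].v.mean()) ** 2).sum()
            for a in df.fa.unique() for b in df.fb.unique())
        df_err = len(df) - na * nb
        by_name = {e.effect: e for e in effects}
        assert by_name["fa"].F == pytest.approx((ss_a / (na - 1)) / (ss_err / df_err), rel=1e-6)
        assert by_name["fb"].F == pytest.approx((ss_b / (nb - 1)) / (ss_err / df_err), rel=1e-6)
        assert by_name["interaction"].F == pytest.approx(
            (ss_ab / ((na - 1) * (nb - 1))) / (ss_err / df_err), rel=1e-6)

    def test_interaction_f_zero_for_equal_cell_means(self):
        # every cell holds exact copies of the same values: all cell means
        # coincide, so every effect's sum of squares vanishes exactly
        rows = []
        for a in ("n", "h"):
            for b in ("x", "y"):
                for i, v in enumerate((1.0, 2.0, 3.0)):
                    rows.append({"animal_id": f"{a}{b}{i}", "fa": a, "fb": b, "v": v})
        effects, _ = two_way_anova(pd.DataFrame(rows), "v", "fa", "fb")
        inter = next(e for e in effects if e.effect == "interaction")
        assert inter.F == pytest.approx(0.0, abs=1e-9)

    def test_repeated_two_levels_epsilon_one(self, rng):
        df = balanced_mixed_design(rng)
        df = df[df.stimulus != "post"]
        effects, _ = two_way_anova(df, "v", "genotype", "stimulus",
                                   repeated_on="stimulus")
        within = next(e for e in effects if e.effect == "stimulus")
        assert within.epsilon == pytest.approx(1.0, abs=1e-12)

    def test_mixed_design_interaction_triggers_sidak(self, rng):
        df = balanced_mixed_design(rng, interaction=1.0)
        effects, posthoc = two_way_anova(df, "v", "genotype", "stimulus",
                                         repeated_on="stimulus")
        inter = next(e for e in effects if e.effect == "interaction")
        assert inter.p < 0.05
        assert posthoc.method == "sidak"
        within = next(e for e in effects if e.effect == "stimulus")
        assert within.epsilon is not None and 0 < within.epsilon <= 1

    def test_sidak_adjustment_monotone_and_above_raw(self):
        for p in (0.001, 0.02, 0.2, 0.9):
            assert sidak_adjust(p, 6) >= p
        adj = [sidak_adjust(p, 6) for p in (0.01, 0.05, 0.2)]
        assert adj == sorted(adj)


class TestRmAnovaDunnett:
    @staticmethod
    def bins_table(rng, n=10, shifts=None):
        shifts = shifts or {}
        labels = ["baseline"] + [str(k) for k in range(1, 7)]
        rows = []
        for a in range(n):
            base = rng.normal(1.0, 0.05)
            for lab in labels:
                rows.append({
                    "animal_id": f"a{a}", "bin_label": lab,
                    "eye_opening": base + shifts.get(lab, 0.0) + rng.normal(0, 0.05),
                })
        return pd.DataFrame(rows)

    def test_copies_of_baseline_give_f_zero_p_one(self):
        rows = []
        for a in range(6):
            value = 1.0 + 0.1 * a
            for lab in ["baseline"] + [str(k) for k in range(1, 7)]:
                rows.append({"animal_id": f"a{a}", "bin_label": lab,
                             "eye_opening": value})
        anova, posthoc = rm_anova_dunnett(pd.DataFrame(rows), "eye_opening")
        assert anova.F == pytest.approx(0.0, abs=1e-12)
        assert all(p == pytest.approx(1.0) for p in posthoc.p_adj)

    def test_uncorrected_df_arithmetic(self, rng):
        anova, _ = rm_anova_dunnett(self.bins_table(rng, n=10), "eye_opening")
        # 7 within levels, 10 subjects: df (6, 54) before the epsilon correction
        assert anova.df1 / anova.epsilon == pytest.approx(6, abs=1e-9)
        assert anova.df2 / anova.epsilon == pytest.approx(54, abs=1e-9)

    def test_biphasic_effect_flagged(self, rng):
        hits = 0
        misses = 0
        for _ in range(40):
            bins = self.bins_table(rng, n=10, shifts={"1": 0.25, "5": 0.2, "6": 0.2})
            _, posthoc = rm_anova_dunnett(bins, "eye_opening")
            p = dict(zip([a for a, _ in posthoc.pairs], posthoc.p_adj))
            if p["1"] < 0.05 and p["5"] < 0.05 and p["6"] < 0.05:
                hits += 1
            misses += sum(p[k] < 0.05 for k in ("2", "3", "4"))
        assert hits >= 36  # >= 90% of replicates flag the injected bins
        assert misses <= 0.05 * 3 * 40 + 2 * math.sqrt(0.05 * 0.95 * 3 * 40)

    def test_incomplete_subjects_dropped_with_warning(self, rng):
        bins = self.bins_table(rng, n=5)
        bins = bins[~((bins.animal_id == "a0") & (bins.bin_label == "3"))]
        with pytest.warns(UserWarning, match="dropped 1 subject"):
            rm_anova_dunnett(bins, "eye_opening")

    def test_too_few_complete_subjects_errors(self, rng):
        bins = self.bins_table(rng, n=2)
        with pytest.raises(ValueError, match=">= 3"):
            rm_anova_dunnett(bins, "eye_opening")

    def test_dunnett_adjusted_at_least_paired_t(self, rng):
        from scipy import stats as sps
        wide = rng.normal(1.0, 0.1, size=(12, 4))
        wide[:, 1] += 0.1
        t_stats, p_adj, df_err = dunnett_rm_pvalues(wide)
        assert df_err == 11 * 3
        # adjusted many-to-one p must dominate the unadjusted t probability
        for j, (t, p) in enumerate(zip(t_stats, p_adj), start=1):
            p_raw = 2 * sps.t.sf(abs(t), df_err)
            assert p >= p_raw - 1e-6


class TestICC:
    def test_duplicated_raters_give_one(self):
        items = np.arange(10, dtype=float)
        mat = pd.DataFrame({"r1": items, "r2": items})
        assert icc(mat).value == pytest.approx(1.0, abs=1e-9)

    def test_matches_variance_component_closed_form(self, rng):
        n, k = 20, 3
        items = rng.normal(0, 1.0, size=(n, 1))
        raters = rng.normal(0, 0.3, size=(1, k))
        noise = rng.normal(0, 0.2, size=(n, k))
        mat = pd.DataFrame(items + raters + noise)
        value = icc(mat).value
        # closed form from the two-way ANOVA mean squares
        grand = mat.to_numpy().mean()
        row_means = mat.mean(axis=1).to_numpy()
        col_means = mat.mean(axis=0).to_numpy()
        msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
        msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
        resid = mat.to_numpy() - row_means[:, None] - col_means[None, :] + grand
        mse = (resid**2).sum() / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert value == pytest.approx(expected, abs=1e-9)

    def test_independent_noise_gives_near_zero(self):
        hits = 0
        for seed in range(20):
            mat = pd.DataFrame(np.random.default_rng(seed).normal(0, 1, (200, 3)))
            hits += abs(icc(mat).value) < 0.2
        assert hits >= 19

    def test_constant_ratings_error(self):
        mat = pd.DataFrame(np.ones((10, 3)))
        with pytest.raises(DegenerateSampleError):
            icc(mat)


class TestCorrelationAndWelch:
    def test_perfect_linear_relation(self):
        x = np.arange(10, dtype=float)
        r = pearson_control(x, 2 * x + 1)
        assert r.rho == pytest.approx(1.0, abs=1e-12)

    def test_independent_t_matches_formula(self, rng):
        x, y = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
        r = pearson_control(x, y)
        assert abs(r.rho) < 0.5
        assert r.t == pytest.approx(r.rho * math.sqrt(48 / (1 - r.rho**2)), abs=1e-12)
        assert r.df == 48

    def test_reported_correlation_t_consistency(self):
        # t = rho * sqrt(df / (1 - rho^2)) at rho 0.20, n = 121
        t = 0.20 * math.sqrt(119 / (1 - 0.04))
        assert t == pytest.approx(2.24, abs=0.02)

    def test_welch_identical_groups(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0, abs=1e-12)

    def test_welch_satterthwaite_limit(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.permutation(a) + 0.5  # equal variance, equal n
        r = welch_t(a, b)
        assert r.df == pytest.approx(18.0, abs=1e-9)

    def test_welch_matches_scipy_oracle(self, rng):
        from scipy import stats as sps
        a, b = rng.normal(0, 1, 8), rng.normal(1, 4, 15)
        r = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert r.t == pytest.approx(float(ref.statistic), abs=1e-9)
        assert r.df == pytest.approx(float(ref.df), abs=1e-9)
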