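"""Inferential layer: ANOVA identities, test selection, mixed models."""

import numpy as np
import pandas as pd
import pytest

from conftest import wilcoxon_oracle

from gazereach.exceptions import ConfigurationError
from gazereach.stats import (
    MixedAnova,
    RandomInterceptModel,
    compare_blocks,
    compare_groups,
    fit_random_intercept_model,
    mixed_anova,
    wilcoxon_signed_rank,
)


def random_split_plot(n_per_group=25, k=2, seed=0, effect=0.0, eps_break=0.0):
    """Long-format table: 2 groups × k within levels."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(2 * n_per_group):
        g = "right" if p % 2 == 0 else "left"
        subj = rng.normal(0, 1.0)
        base = rng.normal(0, 1.0, k)
        for b in range(k):
            scale = 1.0 + eps_break * b  # heteroscedastic levels break sphericity
            rows.append(
                {
                    "participant": p,
                    "group": g,
                    "block": f"b{b}",
                    "y": subj + effect * b + base[b] * scale,
                }
            )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_df_structure_matches_cohort_size(self):
        """50 participants in two groups give between-effect df (1, 48)."""
        res = mixed_anova(random_split_plot(25), "y", "block", "participant", "group")
        e = res.effects["between"]
        assert (e.df1, e.df2) == (1, 48)
        assert res.effects["within"].df2 == 48

    def test_ss_conservation(self):
        for seed in range(10):
            k = 2 + seed % 3
            res = mixed_anova(
                random_split_plot(8, k=k, seed=seed), "y", "block", "participant", "group"
            )
            assert res.ss_total == pytest.approx(sum(res.ss_components.values()), rel=1e-10)

    def test_partial_eta_squared_in_unit_interval(self):
        res = mixed_anova(random_split_plot(10, k=3, seed=3), "y", "block",
                          "participant", "group")
        for e in res.effects.values():
            assert 0.0 <= e.partial_eta_sq <= 1.0

    def test_hand_computed_toy_table(self):
        """4 participants × 2 blocks: SS from the raw cell-mean decomposition."""
        # participants 0,1 in group A; 2,3 in group B
        y = {  # (participant, block): value
            (0, 0): 1.0, (0, 1): 2.0, (1, 0): 3.0, (1, 1): 5.0,
            (2, 0): 2.0, (2, 1): 6.0, (3, 0): 4.0, (3, 1): 7.0,
        }
        rows = [
            {"participant": p, "group": "A" if p < 2 else "B", "block": f"b{b}",
             "y": v}
            for (p, b), v in y.items()
        ]
        res = mixed_anova(pd.DataFrame(rows), "y", "block", "participant", "group")
        vals = np.array(list(y.values()))
        grand = vals.mean()  # 3.75
        subj = {p: (y[(p, 0)] + y[(p, 1)]) / 2 for p in range(4)}
        grp = {"A": (subj[0] + subj[1]) / 2, "B": (subj[2] + subj[3]) / 2}
        ss_A = 2 * 2 * sum((grp[g] - grand) ** 2 for g in ("A", "B"))
        ss_SA = 2 * sum((subj[p] - grp["A" if p < 2 else "B"]) ** 2 for p in range(4))
        blk = {b: np.mean([y[(p, b)] for p in range(4)]) for b in (0, 1)}
        ss_B = 4 * sum((blk[b] - grand) ** 2 for b in (0, 1))
        cell = {(g, b): np.mean([y[(p, b)] for p in ((0, 1) if g == "A" else (2, 3))])
                for g in ("A", "B") for b in (0, 1)}
        ss_AB = sum(
            2 * (cell[(g, b)] - grp[g] - blk[b] + grand) ** 2
            for g in ("A", "B") for b in (0, 1)
        )
        ss_total = ((vals - grand) ** 2).sum()
        ss_err = ss_total - ss_A - ss_SA - ss_B - ss_AB
        assert res.ss_components["between"] == pytest.approx(ss_A)
        assert res.ss_components["subjects_within_groups"] == pytest.approx(ss_SA)
        assert res.ss_components["within"] == pytest.approx(ss_B)
        assert res.ss_components["interaction"] == pytest.approx(ss_AB)
        assert res.ss_components["error_within"] == pytest.approx(ss_err)
        assert res.effects["within"].F == pytest.approx((ss_B / 1) / (ss_err / 2))

    def test_within_F_equals_paired_t_squared_single_group(self):
        """With no between factor and k = 2, the within F is the paired t²."""
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 20)
        b = a + rng.normal(0.3, 0.8, 20)
        rows = [
            {"participant": p, "block": blk, "y": v}
            for p, (va, vb) in enumerate(zip(a, b))
            for blk, v in (("b0", va), ("b1", vb))
        ]
        res = MixedAnova(pd.DataFrame(rows), "y", "block", "participant").fit()
        t = sps.ttest_rel(a, b).statistic
        assert res.effects["within"].F == pytest.approx(t**2, rel=1e-10)

    def test_gg_correction_arithmetic(self):
        """Corrected dfs are ε·df: with k = 3 and 50 subjects, df2 = 96 ε."""
        res = mixed_anova(
            random_split_plot(25, k=3, seed=7, eps_break=1.5),
            "y", "block", "participant", "group", sphericity="always",
        )
        e = res.effects["within"]
        assert e.corrected
        assert e.df1 == pytest.approx(2 * res.epsilon)
        assert e.df2 == pytest.approx(96 * res.epsilon)
        assert 0.5 <= res.epsilon <= 1.0

    def test_epsilon_and_mauchly_match_pingouin(self):
        import pingouin as pg

        df = random_split_plot(12, k=3, seed=11, eps_break=2.0)
        res = mixed_anova(df, "y", "block", "participant", "group")
        spher = pg.sphericity(df, dv="y", within="block", subject="participant")
        eps = pg.epsilon(df, dv="y", within="block", subject="participant",
                         correction="gg")
        # pingouin pools over subjects ignoring group; allow small slack
        assert res.epsilon == pytest.approx(float(eps), abs=0.05)
        assert res.mauchly[0] == pytest.approx(float(spher.W), abs=0.05)

    def test_f_and_p_match_pingouin_two_level(self):
        import pingouin as pg

        df = random_split_plot(15, k=2, seed=13, effect=0.4)
        res = mixed_anova(df, "y", "block", "participant", "group")
        pgres = pg.mixed_anova(
            df, dv="y", within="block", subject="participant", between="group"
        ).set_index("Source")
        assert res.effects["between"].F == pytest.approx(
            float(pgres.loc["group", "F"]), rel=1e-6
        )
        assert res.effects["within"].F == pytest.approx(
            float(pgres.loc["block", "F"]), rel=1e-6
        )
        assert res.effects["interaction"].p == pytest.approx(
            float(pgres.loc["Interaction", "p_unc"]), rel=1e-6
        )

    def test_missing_cell_names_subject(self):
        df = random_split_plot(4).iloc[:-1]
        with pytest.raises(ConfigurationError, match="7"):
            mixed_anova(df, "y", "block", "participant", "group")


class TestComparisons:
    def test_wilcoxon_matches_exhaustive_enumeration(self):
        """Statistic and exact p equal sign-assignment enumeration, n ≤ 10."""
        rng = np.random.default_rng(1)
        cases = [np.array([1.0, 2.0, 3.0, -1.0, 4.0])]
        for _ in range(20):
            n = rng.integers(4, 11)
            cases.append(rng.normal(0.4, 1.0, n))
        for d in cases:
            res = wilcoxon_signed_rank(d)
            w, p = wilcoxon_oracle(d)
            assert res.statistic == pytest.approx(w)
            assert res.p == pytest.approx(p, rel=1e-9)

    def test_gaussian_differences_select_paired_t(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 50)
        b = a + rng.normal(0.2, 0.5, 50)
        res = compare_blocks(a, b)
        assert res.test_used == "t_paired"
        assert res.df == 49

    def test_outlier_differences_select_wilcoxon_with_z(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.1, 50)
        b = a - 0.05 - np.abs(rng.standard_cauchy(50))  # heavy-tailed shift
        res = compare_blocks(a, b)
        assert res.test_used == "wilcoxon_signed_rank"
        assert res.z is not None  # n > 25 uses the normal approximation

    def test_identical_vectors_degenerate_with_warning(self):
        x = np.arange(5.0)
        with pytest.warns(UserWarning):
            res = compare_blocks(x, x.copy())
        assert res.p == 1.0 and "degenerate" in res.note

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_blocks([1.0, 2.0], [2.0, 1.0])

    def test_group_t_is_pooled_with_additive_df(self):
        """25 + 25 participants give df = 48; equal means give t = 0."""
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 25), rng.normal(0, 1, 25)
        assert compare_groups(a, b).df == 48
        x = np.array([1.0, 2.0, 3.0])
        assert compare_groups(x, x[::-1]).statistic == pytest.approx(0.0)

    def test_group_t_matches_hand_formula_on_toy(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert compare_groups(a, b).statistic == pytest.approx(t_hand)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_groups([1.0, 1.0], [1.0, 1.0])


def simulate_lmm(seed, n_groups=25, per=16, beta=(1.83, -0.20, -0.18, 0.17),
                 sd_b=0.6, sd_e=0.9, contaminate=0.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), per)
    gaze = rng.normal(0, 0.7, g.size)
    block = rng.integers(0, 2, g.size).astype(float)
    bias = (g % 2).astype(float)
    b = rng.normal(0, sd_b, n_groups)
    y = beta[0] + beta[1] * gaze + beta[2] * block + beta[3] * bias + b[g]
    y = y + rng.normal(0, sd_e, g.size)
    if contaminate > 0:
        hit = rng.random(g.size) < contaminate
        y[hit] += 15.0 * sd_e  # gross asymmetric errors
    return pd.DataFrame(
        {"participant": g, "y": y, "anticipatory_gaze": gaze,
         "biased_block": block, "directionality_bias": bias}
    )


PREDICTORS = ["anticipatory_gaze", "biased_block", "directionality_bias"]


class TestRandomInterceptModel:
    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        df = simulate_lmm(0)
        mine = fit_random_intercept_model(df, "y", PREDICTORS)
        sm = smf.mixedlm(
            "y ~ anticipatory_gaze + biased_block + directionality_bias",
            df, groups=df["participant"],
        ).fit(reml=True)
        assert np.allclose(mine.params.values, sm.params.values[:4], rtol=1e-4, atol=1e-6)
        assert np.allclose(mine.bse.values, sm.bse.values[:4], rtol=1e-2)
        assert mine.random_intercept_sd == pytest.approx(
            np.sqrt(sm.cov_re.iloc[0, 0]), rel=2e-2
        )
        assert mine.scale == pytest.approx(np.sqrt(sm.scale), rel=1e-3)

    def test_zero_variance_ratio_equals_ols(self):
        df = simulate_lmm(1)
        X = np.column_stack([np.ones(len(df))] + [df[p] for p in PREDICTORS])
        ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        model = RandomInterceptModel.from_dataframe(df, "y", PREDICTORS)
        res = model.fit(variance_ratio=0.0)
        assert np.allclose(res.params.values, ols, atol=1e-6)
        assert res.random_intercept_sd == 0.0

    def test_significance_is_ci_exclusion_of_zero(self):
        res = fit_random_intercept_model(simulate_lmm(2), "y", PREDICTORS)
        for name in res.params.index:
            expect = res.ci_low[name] > 0 or res.ci_high[name] < 0
            assert bool(res.significant[name]) == expect

    def test_robust_less_biased_under_contamination(self):
        """5% gross one-sided errors: Huber weighting shrinks the bias of
        every fixed effect's average estimate."""
        truth = np.array([1.83, -0.20, -0.18, 0.17])
        est_plain, est_robust = [], []
        for seed in range(25):
            df = simulate_lmm(100 + seed, contaminate=0.05)
            model = RandomInterceptModel.from_dataframe(df, "y", PREDICTORS)
            est_plain.append(model.fit().params.values)
            est_robust.append(model.fit(robust=True).params.values)
        bias_plain = np.abs(np.mean(est_plain, axis=0) - truth)
        bias_robust = np.abs(np.mean(est_robust, axis=0) - truth)
        # the contamination is a pure intercept shift; check it there and in
        # total
        assert bias_robust[0] < bias_plain[0]
        assert bias_robust.sum() < bias_plain.sum()

    def test_wald_ci_coverage_near_nominal(self):
        """95% CIs for the gaze slope cover the truth at ≈ the nominal rate
        (Table-1-scale generative coefficients)."""
        truth = -0.20
        hits = 0
        n_rep = 300
        for seed in range(n_rep):
            df = simulate_lmm(1000 + seed)
            res = fit_random_intercept_model(df, "y", PREDICTORS)
            hits += res.ci_low["anticipatory_gaze"] <= truth <= res.ci_high["anticipatory_gaze"]
        coverage = hits / n_rep
        assert 0.90 <= coverage <= 0.985

    def test_robust_summary_has_table_layout(self):
        res = fit_random_intercept_model(simulate_lmm(3), "y", PREDICTORS, robust=True)
        text = res.summary()
        assert "Robust" in text and "Lower 95% CI" in text
        assert "anticipatory_gaze" in text

    def test_too_few_groups_rejected(self):
        df = simulate_lmm(4).query("participant == 0")
        with pytest.raises(ConfigurationError):
            RandomInterceptModel.from_dataframe(df, "y", PREDICTORS)
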