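"""Tests for the group-statistics layer against independent oracles."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from silencescope import stats, synth


class TestLogTransform:
    def test_analytic_values(self):
        out = stats.log_count_transform([0, 99.5])
        assert out[0] == pytest.approx(math.log10(0.5), abs=1e-12)
        assert out[0] == pytest.approx(-0.30103, abs=1e-5)
        assert out[1] == pytest.approx(2.0, abs=1e-12)

    def test_round_trip_exact(self):
        counts = np.array([0, 1, 7, 42, 721, 100000])
        back = stats.inverse_log_count_transform(stats.log_count_transform(counts))
        np.testing.assert_allclose(back, counts, rtol=1e-12, atol=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stats.log_count_transform([-1])


class TestGeometricMean:
    def test_hand_computed_two_point_group(self):
        df = pd.DataFrame({"group": ["a", "a"], "value": [10, 1000]})
        out = stats.geometric_mean_summary(df)
        # mean(log10 10.5, log10 1000.5); closed form sqrt(10.5*1000.5) - 0.5
        assert out["log10_mean"].iloc[0] == pytest.approx(
            (math.log10(10.5) + math.log10(1000.5)) / 2.0, abs=1e-12
        )
        assert out["geometric_mean"].iloc[0] == pytest.approx(
            math.sqrt(10.5 * 1000.5) - 0.5, rel=1e-12
        )

    def test_constant_group(self):
        df = pd.DataFrame({"group": ["a"] * 4, "value": [50] * 4})
        out = stats.geometric_mean_summary(df)
        assert out["geometric_mean"].iloc[0] == pytest.approx(50.0)
        assert out["log10_sem"].iloc[0] == 0.0

    def test_permutation_invariance(self, grouped_df):
        shuffled = grouped_df.sample(frac=1.0, random_state=1)
        a = stats.geometric_mean_summary(grouped_df.assign(value=grouped_df.value + 1))
        b = stats.geometric_mean_summary(shuffled.assign(value=shuffled.value + 1))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stats.geometric_mean_summary(pd.DataFrame({"group": [], "value": []}))


class TestAnova:
    def test_hand_computed_sums_of_squares(self):
        # groups (1,2,3), (2,3,4), (3,4,5): SSB = 6, SSW = 6, F = 3
        df = pd.DataFrame(
            {"group": list("aaabbbccc"), "value": [1, 2, 3, 2, 3, 4, 3, 4, 5]}
        )
        fit = stats.anova_oneway(df)
        assert fit.F == pytest.approx(3.0, abs=1e-12)
        assert (fit.df_between, fit.df_within) == (2, 6)
        assert fit.p == pytest.approx(float(sps.f.sf(3.0, 2, 6)), abs=1e-12)

    def test_two_groups_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 11)
        df = pd.DataFrame(
            {"group": ["a"] * 8 + ["b"] * 11, "value": np.concatenate([a, b])}
        )
        fit = stats.anova_oneway(df)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert fit.F == pytest.approx(t**2, rel=1e-10)
        assert fit.p == pytest.approx(p, rel=1e-10)

    def test_matches_scipy_f_oneway(self, grouped_df):
        fit = stats.anova_oneway(grouped_df)
        arrays = [s["value"].to_numpy() for _, s in grouped_df.groupby("group")]
        F, p = sps.f_oneway(*arrays)
        assert fit.F == pytest.approx(F, rel=1e-10)
        assert fit.p == pytest.approx(p, rel=1e-10)

    def test_matches_statsmodels_linear_model(self, grouped_df):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        lm = smf.ols("value ~ C(group)", grouped_df).fit()
        table = sm.stats.anova_lm(lm)
        fit = stats.anova_oneway(grouped_df)
        assert fit.F == pytest.approx(float(table["F"].iloc[0]), rel=1e-10)

    def test_identical_groups_guarded(self):
        df = pd.DataFrame({"group": list("aabb"), "value": [5.0, 5.0, 5.0, 5.0]})
        fit = stats.anova_oneway(df)
        assert fit.F == 0.0 and fit.p == 1.0

    def test_size_one_group_rejected(self):
        df = pd.DataFrame({"group": ["a", "a", "b"], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="2 observations"):
            stats.anova_oneway(df)

    @given(shift=st.floats(-5, 5))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_order_and_shift_invariance(self, shift):
        df = pd.DataFrame(
            {"group": list("aaabbbccc"), "value": [1, 2, 3, 2, 3, 4, 3, 4, 5]}
        )
        base = stats.anova_oneway(df).F
        moved = stats.anova_oneway(
            df.sample(frac=1.0, random_state=0).assign(value=lambda d: d.value + shift)
        ).F
        assert moved == pytest.approx(base, rel=1e-9)


class TestPosthoc:
    def test_balanced_pair_equals_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        df = pd.DataFrame({"group": ["a"] * 6 + ["b"] * 6, "value": np.concatenate([a, b])})
        fit = stats.anova_oneway(df)
        pw = stats.posthoc_pairwise(df, fit)
        _, p = sps.ttest_ind(a, b, equal_var=True)
        assert pw["p"].iloc[0] == pytest.approx(p, rel=1e-10)

    def test_self_contrast(self, grouped_df):
        fit = stats.anova_oneway(grouped_df)
        pw = stats.posthoc_pairwise(grouped_df, fit, pairs=[("WT", "WT")])
        assert pw["estimate"].iloc[0] == 0.0
        assert pw["p"].iloc[0] == 1.0

    def test_unknown_pair_rejected(self, grouped_df):
        fit = stats.anova_oneway(grouped_df)
        with pytest.raises(ValueError, match="not present"):
            stats.posthoc_pairwise(grouped_df, fit, pairs=[("WT", "nope")])

    def test_holm_correction_monotone(self, grouped_df):
        fit = stats.anova_oneway(grouped_df)
        pw = stats.posthoc_pairwise(grouped_df, fit, correction="holm")
        assert (pw["p_holm"] >= pw["p"] - 1e-15).all()

    def test_large_effect_power(self):
        # WT vs Tg-SN at generator defaults: contrast p < 0.001 in >= 95% of runs
        hits = 0
        for seed in range(40):
            cfg = synth.SimConfig(seed=seed, duration_s=1.0)
            wt = synth.gen_connectivity_counts("WT", 6, cfg, stream=0)
            sn = synth.gen_connectivity_counts("Tg-SN", 5, cfg, stream=1)
            df = pd.concat([wt, sn]).groupby(["starter_id", "group"], observed=True)[
                "count"
            ].sum().reset_index()
            df["value"] = stats.log_count_transform(df["count"])
            fit = stats.anova_oneway(df)
            pw = stats.posthoc_pairwise(df, fit)
            if pw["p"].iloc[0] < 0.001:
                hits += 1
        assert hits >= 38  # 95% of 40


class TestLmm:
    @staticmethod
    def _table(rng, mouse_sd, n_groups=4, mice=5, segs=6, effect=0.0):
        rows = []
        for gi in range(n_groups):
            for m in range(mice):
                mouse = f"g{gi}-m{m}"
                eff = rng.normal(0, mouse_sd) if mouse_sd else 0.0
                vals = 0.4 + gi * effect + eff + rng.normal(0, 0.08, segs)
                rows += [(mouse, f"g{gi}", v) for v in vals]
        return pd.DataFrame(rows, columns=["mouse", "group", "density"])

    def test_degenerate_limit_agrees_with_anova(self, rng):
        # force the REML mouse variance onto its zero boundary by making all
        # mouse means within a group identical; then GLS reduces to OLS and
        # the mixed-model F must match the segment-level ANOVA F
        df = self._table(rng, mouse_sd=0.0, effect=0.1)
        centred = df.copy()
        mouse_mean = centred.groupby("mouse")["density"].transform("mean")
        group_mean = centred.groupby("group")["density"].transform("mean")
        centred["density"] = centred["density"] - mouse_mean + group_mean
        lmm = stats.lmm_spine_density(centred)
        fit = stats.anova_oneway(centred, value="density", group="group")
        assert lmm.mouse_var == pytest.approx(0.0, abs=1e-8)
        assert lmm.F == pytest.approx(fit.F, rel=0.05)

    def test_variance_recovery_within_25pct(self, rng):
        # single draws at 10 mice have ~25% sampling spread on the variance
        # itself, so check the mean over independent replicates
        ests = []
        for _ in range(20):
            df = self._table(rng, mouse_sd=0.1, mice=10, segs=6)
            ests.append(stats.lmm_spine_density(df).mouse_var)
        assert np.mean(ests) == pytest.approx(0.01, rel=0.25)

    def test_detects_group_effect(self, rng):
        df = self._table(rng, mouse_sd=0.02, effect=0.15)
        lmm = stats.lmm_spine_density(df)
        assert lmm.p < 0.001

    def test_single_mouse_rejected(self):
        df = pd.DataFrame(
            {"mouse": ["m1"] * 6, "group": ["a"] * 3 + ["b"] * 3, "density": range(6)}
        )
        with pytest.raises(ValueError, match="single mouse"):
            stats.lmm_spine_density(df)

    def test_mouse_in_two_groups_rejected(self):
        df = pd.DataFrame(
            {
                "mouse": ["m1", "m1", "m2", "m2"],
                "group": ["a", "b", "a", "b"],
                "density": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(ValueError, match="multiple groups"):
            stats.lmm_spine_density(df)
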