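"""Correlation filter, factorial ANOVA, protected LSD and Cohen's d.

The ANOVA path is checked against an independent brute-force sum-of-squares
decomposition computed from group means on small balanced fixtures.
"""

import math

import numpy as np
import pandas as pd
import pytest

from cccfp.stats import (SensitivityAnova, StatsError, cohens_d,
                         correlation_filter, effect_size_label, fit_anova,
                         protected_lsd, run_sensitivity_test,
                         significance_stars)
from cccfp.synthesis import EffectSpec, generate_feature_table


def two_way_oracle(df, response, fa, fb):
    """Brute-force two-way ANOVA decomposition from cell means (balanced)."""
    grand = df[response].mean()
    ss = {}
    for f in (fa, fb):
        ss[f] = sum(len(g) * (g[response].mean() - grand) ** 2
                    for _, g in df.groupby(f))
    inter = 0.0
    means_a = df.groupby(fa)[response].mean()
    means_b = df.groupby(fb)[response].mean()
    for (la, lb), cell in df.groupby([fa, fb]):
        expected = means_a[la] + means_b[lb] - grand
        inter += len(cell) * (cell[response].mean() - expected) ** 2
    ss[f"{fa}:{fb}"] = inter
    resid = sum(((cell[response] - cell[response].mean()) ** 2).sum()
                for _, cell in df.groupby([fa, fb]))
    ss["Residual"] = resid
    return ss


def small_fixture(rng, n_rep=3):
    rows = []
    for a in ("x", "y"):
        for b in ("u", "v"):
            for _ in range(n_rep):
                rows.append({"A": a, "B": b,
                             "y": rng.normal(1.0 + (a == "x") * 0.8
                                             + (b == "u") * 0.3, 1.0)})
    return pd.DataFrame(rows)


class TestCohensD:
    def test_hand_computed_value(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_antisymmetry_and_affine_invariance(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 40)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))
        assert cohens_d(2 * a + 5, 2 * b + 5) == pytest.approx(cohens_d(a, b))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(StatsError):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    @pytest.mark.parametrize("d,label", [
        (0.1, "negligible"), (0.3, "small"), (-0.6, "medium"), (1.2, "large"),
    ])
    def test_magnitude_labels(self, d, label):
        assert effect_size_label(d) == label


class TestCorrelationFilter:
    def test_identical_columns_one_dropped(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        report = correlation_filter(df)
        assert len(report.kept) == 2 and "c" in report.kept
        assert set(report.dropped) <= {"a", "b"}

    def test_independent_noise_all_kept(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 6)),
                          columns=list("abcdef"))
        report = correlation_filter(df)
        assert len(report.kept) == 6

    def test_no_kept_pair_exceeds_threshold(self, rng):
        base = rng.normal(size=100)
        df = pd.DataFrame({
            "a": base, "b": base + rng.normal(0, 0.3, 100),
            "c": base + rng.normal(0, 0.4, 100), "d": rng.normal(size=100)})
        report = correlation_filter(df, threshold=0.7)
        sub = report.correlation.loc[list(report.kept), list(report.kept)]
        off = sub.to_numpy()[~np.eye(len(report.kept), dtype=bool)]
        assert (np.abs(off) <= 0.7).all()

    def test_constant_column_dropped_with_warning(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        with pytest.warns(UserWarning, match="constant column"):
            report = correlation_filter(df)
        assert report.dropped["b"] == "<constant>"


class TestFitAnova:
    def test_matches_brute_force_decomposition(self, rng):
        df = small_fixture(rng)
        effects = {e.name: e for e in fit_anova(df, "y", ["A", "B"])}
        oracle = two_way_oracle(df, "y", "A", "B")
        for name, ss in oracle.items():
            assert effects[name].sum_sq == pytest.approx(ss, rel=1e-8)

    def test_balanced_type1_equals_type2(self, rng):
        df = small_fixture(rng, n_rep=4)
        t1 = {e.name: e.sum_sq for e in fit_anova(df, "y", ["A", "B"], typ=1)}
        t2 = {e.name: e.sum_sq for e in fit_anova(df, "y", ["A", "B"], typ=2)}
        for name in t1:
            assert t1[name] == pytest.approx(t2[name], rel=1e-8)

    def test_degenerate_perfect_effect_reports_inf_sentinel(self):
        rows = [{"A": a, "B": b, "y": 1.0 if a == "x" else 0.0}
                for a in ("x", "y") for b in ("u", "v") for _ in range(3)]
        effects = {e.name: e for e in fit_anova(pd.DataFrame(rows), "y",
                                                ["A", "B"])}
        assert math.isinf(effects["A"].F) and effects["A"].p == 0.0
        assert effects["B"].F == 0.0 and effects["B"].p == 1.0

    def test_aliased_factors_rejected(self, rng):
        df = small_fixture(rng)
        df["A2"] = df["A"].map({"x": "p", "y": "q"})
        with pytest.raises(StatsError, match="aliased"):
            fit_anova(df, "y", ["A", "A2"])

    def test_type_one_error_calibrated_under_null(self):
        # fraction of p < 0.01 for a main effect over null simulations
        hits, n_sims, alpha = 0, 1000, 0.01
        rng = np.random.default_rng(77)
        a = np.repeat(["x", "y"], 12)
        b = np.tile(np.repeat(["u", "v"], 6), 2)
        for _ in range(n_sims):
            df = pd.DataFrame({"A": a, "B": b, "y": rng.normal(size=24)})
            effects = {e.name: e for e in fit_anova(df, "y", ["A", "B"])}
            hits += effects["A"].p < alpha
        se = math.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(hits / n_sims - alpha) <= 3 * se


class TestProtectedLsd:
    def test_non_significant_f_empty_table(self, rng):
        df = small_fixture(rng)
        df["y"] = rng.normal(size=len(df))  # pure noise
        anova = fit_anova(df, "y", ["A", "B"])
        by = {e.name: e for e in anova}
        if by["A"].p >= 0.01:
            assert len(protected_lsd(df, anova, "y", "A")) == 0

    def test_two_level_t_squared_equals_f(self, rng):
        df = small_fixture(rng, n_rep=6)
        df["y"] += (df["A"] == "x") * 5.0  # strong effect triggers LSD
        anova = fit_anova(df, "y", ["A", "B"])
        by = {e.name: e for e in anova}
        table = protected_lsd(df, anova, "y", "A", alpha=0.01)
        assert len(table) == 1
        assert table["t"].iloc[0] ** 2 == pytest.approx(by["A"].F, rel=1e-8)

    def test_outlying_group_has_smallest_pairwise_p(self, rng):
        rows = []
        for level, mu in (("a", 0.0), ("b", 0.2), ("c", 5.0)):
            for _ in range(10):
                rows.append({"g": level, "B": "u" if rng.random() < 0.5 else "v",
                             "y": rng.normal(mu, 1)})
        df = pd.DataFrame(rows)
        anova = fit_anova(df, "y", ["g", "B"])
        table = protected_lsd(df, anova, "y", "g", alpha=0.01)
        table = table.set_index(["level_a", "level_b"])
        assert table.loc[("a", "c"), "p"] < table.loc[("a", "b"), "p"]
        assert table.loc[("b", "c"), "p"] < table.loc[("a", "b"), "p"]

    def test_absent_factor_rejected(self, rng):
        df = small_fixture(rng)
        anova = fit_anova(df, "y", ["A", "B"])
        with pytest.raises(StatsError):
            protected_lsd(df, anova, "y", "missing")


class TestSensitivityAnova:
    def test_pure_subspecies_effect_detected_without_flags(self, full_design):
        spec = EffectSpec(effects={"l250": {"subspecies": 2.0}}, seed=3)
        feats = generate_feature_table(full_design, spec)
        res = run_sensitivity_test(feats, full_design, "subspecies")
        assert res["l250"].p < 0.01
        assert res["l250"].interactions == ""
        assert res["l250"].effect_size == pytest.approx(2.0, abs=0.45)

    def test_deciduous_test_uses_192_rows(self, full_design):
        feats = generate_feature_table(full_design, EffectSpec(seed=1))
        model = SensitivityAnova(feats, full_design, "deciduous")
        assert len(model.data) == 192

    def test_protection_holds_globally(self, full_design):
        feats = generate_feature_table(full_design, EffectSpec(seed=8))
        for test_id in ("subspecies", "deciduous", "blending"):
            res = run_sensitivity_test(feats, full_design, test_id)
            for var, r in res.per_variable.items():
                if r.p >= 0.01:
                    assert len(r.lsd) == 0, (test_id, var)

    def test_day_interaction_flag_and_drilldown(self, full_design):
        # subspecies effect present only on days 1-3 -> day interaction
        frame = full_design.frame
        feats = generate_feature_table(full_design, EffectSpec(seed=5))
        boost = ((frame["subspecies"] == "VAA") & (frame["day"] <= 3)) * 3.0
        feats = feats.copy()
        feats["entropy"] = feats["entropy"] + boost.to_numpy()
        res = run_sensitivity_test(feats, full_design, "subspecies",
                                   variables=("entropy",))
        assert "d" in res["entropy"].interactions
        drill = res["entropy"].per_day
        assert drill is not None
        sig_days = set(drill.loc[drill["significant"], "day"])
        assert sig_days == {1, 2, 3}

    def test_summary_table_layout(self, full_design):
        spec = EffectSpec(effects={"l250": {"subspecies": 1.5}}, seed=2)
        feats = generate_feature_table(full_design, spec)
        summ = run_sensitivity_test(feats, full_design, "subspecies").summary()
        assert list(summ.columns) == ["variable", "p", "stars", "effect_size",
                                      "effect_label", "interactions"]
        assert len(summ) == 7
        row = summ.set_index("variable").loc["l250"]
        assert row["stars"] in ("*", "**", "***")

    def test_missing_features_rejected(self, full_design):
        feats = generate_feature_table(full_design, EffectSpec(seed=1)).iloc[:100]
        with pytest.raises(StatsError, match="does not cover"):
            SensitivityAnova(feats, full_design, "subspecies")


class TestStars:
    @pytest.mark.parametrize("p,stars", [
        (0.5, ""), (0.009, "*"), (0.0009, "**"), (0.00009, "***"),
    ])
    def test_thresholds(self, p, stars):
        assert significance_stars(p) == stars
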