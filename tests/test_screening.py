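"""Nested ANOVA, BLUE, STI and relative-change arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from potpheno import synthetic
from potpheno.screening import (
    UnbalancedDesignError,
    anova_table,
    blue_estimate,
    filter_traits,
    inverse_log_transform,
    k_na_summary,
    log_transform,
    nested_anova,
    relative_change,
    sti,
)
from potpheno.synthetic import TraitEffect, TrialSimSpec, simulate_trial


def toy_table():
    """Fixed 2 genotypes x 2 environments x 3 reps x 1 sample table."""
    rng = np.random.default_rng(1234)
    rows = []
    for geno in ("A", "B"):
        for env in ("normal", "saline"):
            for rep in (1, 2, 3):
                rows.append((geno, env, rep, 1, "x", float(rng.normal(10, 2))))
    return pd.DataFrame(rows, columns=["genotype", "environment", "replicate",
                                       "sample", "trait", "value"])


def oracle_nested_ss(t):
    """Independent sums-of-squares computation via groupby means."""
    g = t["genotype"].nunique()
    e = t["environment"].nunique()
    r = t["replicate"].nunique()
    m = t["value"].mean()
    me = t.groupby("environment")["value"].mean()
    mer = t.groupby(["environment", "replicate"])["value"].mean()
    mg = t.groupby("genotype")["value"].mean()
    mge = t.groupby(["genotype", "environment"])["value"].mean()
    ss = {
        "stress": g * r * ((me - m) ** 2).sum(),
        "rep": g * ((mer - me.reindex(mer.index.get_level_values(0)).values) ** 2).sum(),
        "genotype": e * r * ((mg - m) ** 2).sum(),
        "total": ((t["value"] - m) ** 2).sum(),
    }
    inter = 0.0
    for (geno, env), v in mge.items():
        inter += (v - mg[geno] - me[env] + m) ** 2
    ss["gxs"] = r * inter
    ss["residual"] = ss["total"] - ss["stress"] - ss["rep"] - ss["genotype"] - ss["gxs"]
    df = {"stress": e - 1, "rep": e * (r - 1), "genotype": g - 1,
          "gxs": (g - 1) * (e - 1)}
    df["residual"] = g * e * r - 1 - sum(df.values())
    return ss, df


class TestLogTransform:
    def test_examples(self):
        t = toy_table()
        t.loc[0, "value"] = 9.0
        t.loc[1, "value"] = 0.0
        out = log_transform(t, offset=1.0)
        assert out.loc[0, "value"] == pytest.approx(1.0)
        assert out.loc[1, "value"] == pytest.approx(0.0)

    def test_round_trip(self):
        t = toy_table()
        back = inverse_log_transform(log_transform(t))
        assert np.allclose(back["value"], t["value"], atol=1e-12)

    def test_non_positive_shifted_values_listed(self):
        t = toy_table()
        t.loc[2, "value"] = -5.0
        with pytest.raises(ValueError, match=r"1 row"):
            log_transform(t, offset=1.0)


class TestNestedAnova:
    def test_toy_table_matches_ss_oracle(self):
        t = toy_table()
        res = nested_anova(t).loc["x"]
        ss, df = oracle_nested_ss(t)
        for src in ("stress", "rep", "genotype", "gxs", "residual"):
            assert res[f"ss_{src}" if src != "rep" else "ss_rep"] == pytest.approx(
                ss[src], abs=1e-8)
        f_stress = (ss["stress"] / df["stress"]) / (ss["rep"] / df["rep"])
        assert res["F_stress"] == pytest.approx(f_stress, abs=1e-8)
        assert res["p_stress"] == pytest.approx(
            stats.f.sf(f_stress, df["stress"], df["rep"]), abs=1e-8)
        f_geno = (ss["genotype"] / df["genotype"]) / (ss["residual"] / df["residual"])
        assert res["p_genotype"] == pytest.approx(
            stats.f.sf(f_geno, df["genotype"], df["residual"]), abs=1e-8)

    def test_matches_statsmodels_ols_decomposition(self):
        """Cross-check against an independent OLS ANOVA fit."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        t = toy_table()
        model = smf.ols(
            "value ~ C(environment) + C(environment):C(replicate) "
            "+ C(genotype) + C(genotype):C(environment)", data=t).fit()
        tbl = sm.stats.anova_lm(model, typ=1)
        res = nested_anova(t).loc["x"]
        assert res["ss_stress"] == pytest.approx(
            tbl.loc["C(environment)", "sum_sq"], abs=1e-8)
        assert res["ss_genotype"] == pytest.approx(
            tbl.loc["C(genotype)", "sum_sq"], abs=1e-8)
        assert res["ss_rep"] == pytest.approx(
            tbl.loc["C(environment):C(replicate)", "sum_sq"], abs=1e-8)
        assert res["ss_residual"] == pytest.approx(
            tbl.loc["Residual", "sum_sq"], abs=1e-8)

    def test_ss_partition_identity(self, trial_table):
        res = nested_anova(log_transform(trial_table))
        parts = res[["ss_stress", "ss_rep", "ss_genotype", "ss_gxs",
                     "ss_residual"]].sum(axis=1)
        assert np.allclose(parts, res["ss_total"], atol=1e-8)

    def test_constant_data_reports_p_one(self):
        t = toy_table()
        t["value"] = 3.0
        with pytest.warns(UserWarning, match="zero variance"):
            res = nested_anova(t)
        assert (res[["p_stress", "p_genotype", "p_gxs"]] == 1.0).all().all()

    def test_unbalanced_rejected(self, trial_table):
        broken = trial_table.drop(index=trial_table.index[0])
        with pytest.raises(UnbalancedDesignError):
            nested_anova(broken)

    def test_cv_definition(self):
        t = toy_table()
        res = nested_anova(t).loc["x"]
        ss, df = oracle_nested_ss(t)
        cv = 100 * np.sqrt(ss["residual"] / df["residual"]) / t["value"].mean()
        assert res["cv_trans"] == pytest.approx(cv, abs=1e-8)

    def test_source_table_shape(self):
        tbl = anova_table(toy_table(), "x")
        assert list(tbl.index) == ["stress", "replicate(stress)", "genotype",
                                   "genotype x stress", "residual"]
        assert tbl["df"].sum() == 11


class TestFilterTraits:
    def test_alpha_zero_empty(self):
        a = pd.DataFrame({"p_stress": [0.001, 0.0001]}, index=["a", "b"])
        assert filter_traits(a, alpha=0.0) == []

    def test_all_below_alpha_retained_in_order(self):
        a = pd.DataFrame({"p_stress": [0.04, 0.04, 0.04]}, index=["c", "a", "b"])
        assert filter_traits(a, alpha=0.05) == ["c", "a", "b"]


class TestBlue:
    def test_equals_cell_means_on_balanced_data(self, trial_table):
        blue = blue_estimate(trial_table)
        cell = (trial_table.groupby(["genotype", "environment", "trait"])
                ["value"].mean().reset_index())
        merged = blue.merge(cell, on=["genotype", "environment", "trait"])
        assert np.allclose(merged["value_x"], merged["value_y"], atol=1e-9)

    def test_block_shift_leaves_genotype_differences(self):
        t = toy_table()
        shifted = t.copy()
        shifted.loc[(shifted["replicate"] == 2) & (shifted["environment"] == "normal"),
                    "value"] += 50.0
        b0 = blue_estimate(t).set_index(["genotype", "environment"])["value"]
        b1 = blue_estimate(shifted).set_index(["genotype", "environment"])["value"]
        d0 = b0[("A", "normal")] - b0[("B", "normal")]
        d1 = b1[("A", "normal")] - b1[("B", "normal")]
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_recovers_design_effects_as_noise_vanishes(self):
        geno = (2.0, -2.0, 0.0, 0.0, 0.0, 0.0)
        spec = TrialSimSpec(
            traits={"x": TraitEffect(grand_mean=20.0, stress_effect=6.0,
                                     genotype_effects=geno)},
            block_sd=0.0, residual_sd=1e-9, sd_mode="absolute", seed=0,
        )
        blue = blue_estimate(simulate_trial(spec)).set_index(
            ["genotype", "environment"])["value"]
        assert blue[("DH1", "normal")] == pytest.approx(20 + 3 + 2, abs=1e-6)
        assert blue[("DH2", "saline")] == pytest.approx(20 - 3 - 2, abs=1e-6)


class TestSti:
    @staticmethod
    def _blue(rows):
        return pd.DataFrame(rows, columns=["genotype", "environment", "trait", "value"])

    def test_no_stress_identity(self):
        b = self._blue([("A", "normal", "x", 2.0), ("A", "saline", "x", 2.0),
                        ("B", "normal", "x", 2.0), ("B", "saline", "x", 2.0)])
        assert np.allclose(sti(b).values["x"], 1.0)

    def test_half_performance(self):
        b = self._blue([("A", "normal", "x", 2.0), ("A", "saline", "x", 1.0)])
        assert sti(b).values.loc["A", "x"] == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        b = self._blue([("A", "normal", "x", 4.0), ("A", "saline", "x", 3.0),
                        ("B", "normal", "x", 5.0), ("B", "saline", "x", 2.0)])
        scaled = b.assign(value=b["value"] * c)
        pd.testing.assert_frame_equal(sti(b).values, sti(scaled).values)

    def test_zero_normal_mean_rejected(self):
        b = self._blue([("A", "normal", "x", 1.0), ("A", "saline", "x", 1.0),
                        ("B", "normal", "x", -1.0), ("B", "saline", "x", 1.0)])
        with pytest.raises(ZeroDivisionError, match="x"):
            sti(b)


class TestRelativeChange:
    @staticmethod
    def _blue(rows):
        return pd.DataFrame(rows, columns=["genotype", "environment", "trait", "value"])

    def test_percent_decrease(self):
        b = self._blue([("A", "normal", "x", 4.0), ("A", "saline", "x", 3.0)])
        out = relative_change(b, mode="decrease", scale="percent")
        assert out.loc["A", "x"] == pytest.approx(25.0)
        assert out.attrs == {"mode": "decrease", "scale": "percent"}

    def test_decrease_is_negated_increase(self):
        rng = np.random.default_rng(0)
        rows = []
        for g in "ABCD":
            rows += [(g, "normal", "x", rng.uniform(1, 10)),
                     (g, "saline", "x", rng.uniform(1, 10))]
        b = self._blue(rows)
        dec = relative_change(b, mode="decrease", scale="proportion")
        inc = relative_change(b, mode="increase", scale="proportion")
        assert np.allclose(dec.to_numpy(), -inc.to_numpy(), atol=1e-12)

    def test_zero_normal_rejected(self):
        b = self._blue([("A", "normal", "x", 0.0), ("A", "saline", "x", 1.0)])
        with pytest.raises(ZeroDivisionError):
            relative_change(b)


class TestKNaSummary:
    def test_ratio_arithmetic(self):
        ion = pd.DataFrame([("A", "normal", 1.0, 2.0), ("A", "saline", 2.0, 2.0)],
                           columns=["genotype", "environment", "na", "k"])
        out = k_na_summary(ion)
        assert out.loc["A", "k_na_normal"] == pytest.approx(2.0)
        assert out.loc["A", "k_na_saline"] == pytest.approx(1.0)
        assert out.loc["A", "ri_na"] == pytest.approx(1.0)

    def test_non_positive_na_rejected(self):
        ion = pd.DataFrame([("A", "normal", 0.0, 2.0)],
                           columns=["genotype", "environment", "na", "k"])
        with pytest.raises(ValueError, match="Na"):
            k_na_summary(ion)

    def test_class_ordering_from_generator(self):
        _, ions = synthetic.simulate_physiology(synthetic.PhysioSimSpec(noise_sd=0.0))
        out = k_na_summary(ions)
        classes = synthetic.DEFAULT_TOLERANCE_CLASSES
        tol = out.loc[[g for g, c in classes.items() if c == "tolerant"],
                      "k_na_saline"].min()
        sen = out.loc[[g for g, c in classes.items() if c == "sensitive"],
                      "k_na_saline"].max()
        assert tol > sen
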