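import numpy as np
import pandas as pd
import pytest

from fscv import (
    anova_oneway,
    anova_twoway,
    cv_table,
    default_cohort_design,
    generate_cohort,
    mixed_model_weeks,
    pairwise_posthoc,
    rm_anova_two_way,
    simulate_null_rejection_rate,
)


def _long(values_by_group):
    rows = [
        {"group": g, "y": v} for g, vals in values_by_group.items() for v in vals
    ]
    return pd.DataFrame(rows)


class TestOneWay:
    def test_identical_groups_give_zero_f(self):
        df = _long({"a": [1, 2, 3], "b": [1, 2, 3]})
        res = anova_oneway(df, "y", "group")
        assert res["F"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_group_f(self):
        df = _long({"a": [1, 2, 3], "b": [4, 5, 6]})
        res = anova_oneway(df, "y", "group")
        assert res["F"] == pytest.approx(13.5)
        assert res["df"] == (1, 4)

    def test_tukey_flags_only_shifted_group(self):
        rng = np.random.default_rng(14)
        df = _long(
            {
                "a": rng.normal(0, 1, 30),
                "b": rng.normal(0, 1, 30),
                "c": rng.normal(8, 1, 30),
            }
        )
        res = anova_oneway(df, "y", "group")
        ph = res["posthoc"]
        rejected = ph[ph["reject"] == True]  # noqa: E712
        pairs = {frozenset((r["group1"], r["group2"])) for _, r in rejected.iterrows()}
        assert pairs == {frozenset(("a", "c")), frozenset(("b", "c"))}

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway(_long({"a": [1.0], "b": [1, 2]}), "y", "group")


class TestTwoWayBetween:
    def test_balanced_additive_design(self):
        rng = np.random.default_rng(15)
        rows = []
        for sex, s_eff in (("m", 0.0), ("f", 3.0)):
            for drug, d_eff in (("pre", 0.0), ("post", 1.5)):
                for _ in range(40):
                    rows.append(
                        {"sex": sex, "drug": drug,
                         "y": 10 + s_eff + d_eff + rng.normal()}
                    )
        df = pd.DataFrame(rows)
        res = anova_twoway(df, "y", ("sex", "drug"))
        eff = res["effects"]
        assert eff.loc["sex", "p_unc"] < 1e-6
        assert eff.loc["drug", "p_unc"] < 1e-6
        assert eff.loc["sex * drug", "p_unc"] > 0.01  # no interaction generated

    def test_empty_cell_rejected(self):
        df = pd.DataFrame(
            {"a": ["x", "x", "y"], "b": ["p", "q", "p"], "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="empty cell"):
            anova_twoway(df, "y", ("a", "b"))

    def test_f_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(
            {
                "a": np.repeat(["x", "y"], 20),
                "b": np.tile(np.repeat(["p", "q"], 10), 2),
                "y": rng.normal(5, 2, 40),
            }
        )
        f1 = anova_twoway(df, "y", ("a", "b"))["effects"]["F"]
        df2 = df.assign(y=3.0 * df["y"] + 7.0)
        f2 = anova_twoway(df2, "y", ("a", "b"))["effects"]["F"]
        np.testing.assert_allclose(f1[:3], f2[:3], rtol=1e-9)


class TestRepeatedMeasures:
    def test_sphericity_compliant_covariance_gives_epsilon_one(self):
        """Independent homoscedastic cell noise (compound symmetry) is
        spherical: the Greenhouse–Geisser epsilon stays near its maximum."""
        rng = np.random.default_rng(17)
        n, a, b = 60, 4, 2
        wide = 100 + rng.normal(0, 1, (n, 1)) * 5 + rng.normal(0, 1, (n, a * b))
        eff = rm_anova_two_way(wide, a, b)
        assert (eff["eps"] > 0.85).all()

    def test_manual_route_matches_pingouin(self):
        """The expected-mean-squares implementation and pingouin's
        repeated-measures ANOVA agree on complete balanced data."""
        import pingouin as pg

        design = default_cohort_design(sensitization_slope=0.3, n_animals=3)
        table, _ = generate_cohort(design, seed=5)
        sub = table[table.group == "CAST_male"]
        wide = (
            sub.pivot_table(index="fiber", columns=["week", "param"],
                            values="es_da_nM")
            .sort_index(axis=1)
        )
        mine = rm_anova_two_way(wide.to_numpy(), 4, 2)
        ref = pg.rm_anova(
            data=sub, dv="es_da_nM", within=["week", "param"], subject="fiber",
            correction=True, detailed=True,
        )
        np.testing.assert_allclose(
            mine["F"].to_numpy(), ref["F"].to_numpy()[:3], rtol=1e-9
        )
        np.testing.assert_allclose(
            mine["eps"].to_numpy(), ref["eps"].to_numpy()[:3], rtol=1e-6
        )


class TestMixedModelWeeks:
    def test_complete_data_uses_rm_anova_route(self):
        design = default_cohort_design(sensitization_slope=0.3, n_animals=2)
        table, _ = generate_cohort(design, seed=6)
        res = mixed_model_weeks(table[table.group == "CAST_male"])
        assert res["method"] == "rm_anova"
        eff = res["effects"].set_index("Source")
        assert eff.loc["week", "p_gg"] < 1e-6  # strong true sensitization

    def test_missing_data_uses_mixed_model_and_detects_week(self):
        design = default_cohort_design(
            sensitization_slope=0.3, n_animals=3, missing_rate=0.15
        )
        table, _ = generate_cohort(design, seed=7)
        res = mixed_model_weeks(table[table.group == "CAST_male"], posthoc="tukey")
        assert res["method"] == "mixedlm"
        eff = res["effects"].set_index("Source")
        assert eff.loc["week", "p_unc"] < 1e-4
        ph = res["posthoc"]
        w14 = ph[(ph["A"] == 1) & (ph["B"] == 4)]
        assert bool(w14["significant"].iloc[0])

    def test_equivalence_of_routes_on_complete_data(self):
        """With no missingness the mixed-model entry point reproduces the
        two-way repeated-measures ANOVA F statistics to 3 decimals."""
        design = default_cohort_design(sensitization_slope=0.2, n_animals=3)
        table, _ = generate_cohort(design, seed=8)
        sub = table[table.group == "OVX_female"]
        mm = mixed_model_weeks(sub)["effects"].set_index("Source")
        aov = anova_twoway(
            sub, "es_da_nM", ("week", "param"), repeated=True, subject="fiber"
        )["effects"]
        for src_m, src_a in (
            ("week", "week"), ("param", "param"), ("week * param", "week * param"),
        ):
            f_aov = float(aov.loc[aov["Source"] == src_a, "F"].iloc[0])
            assert mm.loc[src_m, "F"] == pytest.approx(f_aov, abs=1e-3)

    def test_all_missing_fiber_equivalent_to_never_present(self):
        design = default_cohort_design(sensitization_slope=0.1, n_animals=2)
        table, _ = generate_cohort(design, seed=9)
        sub = table[table.group == "CAST_male"].copy()
        victim = sub["fiber"].iloc[0]
        dropped = sub[sub.fiber != victim]
        nan_rows = sub.copy()
        nan_rows.loc[nan_rows.fiber == victim, "es_da_nM"] = np.nan
        a = mixed_model_weeks(dropped)["effects"]
        b = mixed_model_weeks(nan_rows)["effects"]
        np.testing.assert_allclose(a["F"].to_numpy(), b["F"].to_numpy(), rtol=1e-9)


class TestPosthoc:
    def test_sidak_less_conservative_than_bonferroni(self):
        rng = np.random.default_rng(18)
        df = pd.DataFrame(
            {
                "lvl": np.repeat(list("abcd"), 15),
                "y": rng.normal(0, 1, 60) + np.repeat([0, 0.5, 1.0, 1.5], 15),
            }
        )
        bon = pairwise_posthoc(df, "y", "lvl", method="bonferroni")
        sid = pairwise_posthoc(df, "y", "lvl", method="sidak")
        assert (sid["p_adj"] <= bon["p_adj"] + 1e-12).all()


class TestCvTable:
    def test_equal_fibers_give_zero_cv(self):
        df = pd.DataFrame(
            {
                "group": ["g"] * 4, "week": [1] * 4, "param": ["p"] * 4,
                "animal": ["a1", "a1", "a2", "a2"],
                "es_da_nM": [5.0, 5.0, 9.0, 9.0],
            }
        )
        out = cv_table(df)
        assert out["cv_mean"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_cv(self):
        df = pd.DataFrame(
            {
                "group": ["g"] * 3, "week": [1] * 3, "param": ["p"] * 3,
                "animal": ["a1"] * 3, "es_da_nM": [8.0, 10.0, 12.0],
            }
        )
        out = cv_table(df)
        assert out["cv_mean"].iloc[0] == pytest.approx(0.2)

    def test_animal_with_single_fiber_excluded(self):
        df = pd.DataFrame(
            {
                "group": ["g"] * 4, "week": [1] * 4, "param": ["p"] * 4,
                "animal": ["a1", "a1", "a1", "a2"],
                "es_da_nM": [8.0, 10.0, 12.0, 99.0],
            }
        )
        out = cv_table(df)
        assert out["n_animals"].iloc[0] == 1

    def test_generator_cv_target_appears_in_table(self):
        design = default_cohort_design(n_animals=6)
        table, _ = generate_cohort(design, seed=19)
        out = cv_table(table)
        # fiber CV 0.27 plus trial noise CV 0.10 -> cell CVs a little above 0.27
        expected = np.sqrt(0.27**2 + 0.10**2)
        assert out["cv_mean"].mean() == pytest.approx(expected, abs=0.05)


def test_null_week_effect_rejection_rate_calibrated():
    rate = simulate_null_rejection_rate(n_reps=200, seed=30)
    assert 0.02 <= rate <= 0.09
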