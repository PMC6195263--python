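"""Risk tabulation, percentile bootstrap, paired comparison, sensitivity."""

import numpy as np
import pandas as pd
import pytest

import ckdsim as ck
from ckdsim.outcomes import percentile_interval, run_sensitivity
from conftest import cohort_frame, cohort_row


def records_frame(stages, group="normal"):
    stages = list(stages)
    return pd.DataFrame(
        {
            "id": range(len(stages)),
            "baseline_bmi_cat": group,
            "baseline_age_band": "50-64",
            "baseline_egfr_band": "ge60",
            "ever_ckd": [s != "none" for s in stages],
            "highest_stage": stages,
            "age_at_death_or_90": 90.0,
            "died": False,
        }
    )


class TestLifetimeRisk:
    def test_counting(self):
        rec = records_frame(["s1"] * 4 + ["none"] * 6)
        table = ck.lifetime_risk(rec)
        assert table.iloc[0]["risk_any"] == pytest.approx(0.40)
        assert table.iloc[0]["n"] == 10

    def test_all_none_gives_zero_risk(self):
        table = ck.lifetime_risk(records_frame(["none"] * 5))
        assert table.iloc[0]["risk_any"] == 0.0
        assert all(table.iloc[0][f"share_{s}"] == 0.0 for s in ("s1", "s3a", "s5"))

    def test_highest_stage_shares(self):
        table = ck.lifetime_risk(records_frame(["s3a", "s3a", "s4", "none"]))
        row = table.iloc[0]
        assert row["risk_any"] == pytest.approx(0.75)
        assert row["share_s3a"] == pytest.approx(0.50)
        assert row["share_s4"] == pytest.approx(0.25)

    def test_partition_identity(self, small_cohort, bundle):
        rec = ck.simulate_cohort(small_cohort, bundle, master_seed=3)
        table = ck.lifetime_risk(rec, by=("baseline_bmi_cat", "baseline_age_band"))
        shares = table[[f"share_{s}" for s in ("s1", "s2", "s3a", "s3b", "s4", "s5")]]
        np.testing.assert_allclose(shares.sum(axis=1), table["risk_any"], atol=1e-12)

    def test_empty_requested_group_reported_missing(self):
        rec = records_frame(["s1", "none"])
        rec["baseline_bmi_cat"] = pd.Categorical(
            ["normal", "normal"], categories=["normal", "obesity"])
        table = ck.lifetime_risk(rec).set_index("baseline_bmi_cat")
        assert table.loc["obesity", "n"] == 0
        assert np.isnan(table.loc["obesity", "risk_any"])


class TestBootstrap:
    def test_percentile_rule_on_injected_replicates(self):
        values = np.arange(1, 101) / 100.0
        lo, hi = percentile_interval(values)
        assert lo == pytest.approx(0.03475)
        assert hi == pytest.approx(0.97525)

    def test_degenerate_cohort_gives_collapsed_ci(self, bundle):
        # everyone starts at stage 3a: every replicate estimate is 1.0
        rows = [cohort_row(i, 70, 50.0) for i in range(40)]
        table, reps = ck.bootstrap_ci(cohort_frame(rows), bundle, B=10, master_seed=4)
        row = table.iloc[0]
        assert row["risk_any"] == 1.0
        assert row["risk_any_ci_low"] == 1.0 and row["risk_any_ci_high"] == 1.0

    def test_single_replicate_ci_collapses_to_it(self, small_cohort, bundle):
        table, reps = ck.bootstrap_ci(small_cohort, bundle, B=1, master_seed=4)
        reps_by_cat = reps.set_index("baseline_bmi_cat")["risk_any"]
        for _, row in table.iterrows():
            val = reps_by_cat[row["baseline_bmi_cat"]]
            assert row["risk_any_ci_low"] == pytest.approx(val)
            assert row["risk_any_ci_high"] == pytest.approx(val)

    def test_ci_width_shrinks_with_cohort_size(self, bundle):
        """Bootstrap CI width at n=2500 is narrower than at n=250 (fixed B)."""
        widths = {}
        for n in (250, 2500):
            spec = ck.default_cohort_spec(n=n, seed=31)
            coh = ck.adjust_persistent_albuminuria(
                ck.generate_cohort(spec), 0.6, seed=32)
            table, _ = ck.bootstrap_ci(coh, bundle, B=15, master_seed=5,
                                       by=("baseline_egfr_band",))
            row = table.set_index("baseline_egfr_band").loc["ge60"]
            widths[n] = row["risk_any_ci_high"] - row["risk_any_ci_low"]
        assert widths[2500] < widths[250]


class TestCompareGroups:
    def test_identical_replicates_give_p_one(self):
        r = ck.compare_groups([0.3, 0.4, 0.5], [0.3, 0.4, 0.5])
        assert r.p_value == 1.0 and r.mean_diff == 0.0

    def test_mean_two_se_gives_p_0455(self):
        # diffs {1,2,3}: mean 2, sd 1 -> z = 2
        r = ck.compare_groups([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert r.p_value == pytest.approx(0.0455, abs=5e-4)

    def test_constant_offset_with_variance_is_significant(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0.4, 0.01, size=100)
        r = ck.compare_groups(base + 0.05, base + rng.normal(0, 0.001, size=100))
        assert r.p_value < 0.05

    def test_zero_variance_nonzero_diff_flagged(self):
        r = ck.compare_groups([0.5] * 20, [0.4] * 20)
        assert r.zero_variance
        assert r.p_value == pytest.approx(1 / 20)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            ck.compare_groups([0.1, 0.2], [0.1])


@pytest.fixture(scope="module")
def contrast_cohort():
    """Normal-weight and obesity baseline groups, 600 persons each."""
    bands = ("30-49", "50-64", "65-90")
    normal = ck.generate_cohort(ck.default_cohort_spec(
        n=600, seed=71, bmi_cat_weights_by_age_band={
            b: {"underweight": 0, "normal": 1, "overweight": 0, "obesity": 0}
            for b in bands}))
    obese = ck.generate_cohort(ck.default_cohort_spec(
        n=600, seed=72, bmi_cat_weights_by_age_band={
            b: {"underweight": 0, "normal": 0, "overweight": 0, "obesity": 1}
            for b in bands}))
    obese["id"] += 600
    coh = pd.concat([normal, obese], ignore_index=True)
    return ck.adjust_persistent_albuminuria(coh, 0.6, seed=73)


class TestSensitivity:
    def test_structure_and_reference(self, contrast_cohort, bundle):
        table = run_sensitivity(contrast_cohort, bundle, master_seed=6)
        scaled = table[table["parameter"] != "reference"]
        assert len(scaled) == 6
        assert set(scaled["factor"]) == {0.75, 1.25}
        ref = table[table["parameter"] == "reference"]
        assert len(ref) == 1
        assert ref.iloc[0]["diff_any_ckd"] == ref.iloc[0]["reference_diff"]

    def test_identity_factor_reproduces_reference(self, contrast_cohort, bundle):
        scaled = ck.scale_param(bundle, "rr_diabetes_obesity", 1.0)
        a = ck.simulate_cohort(contrast_cohort, bundle, master_seed=6)
        b = ck.simulate_cohort(contrast_cohort, scaled, master_seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_diabetes_rr_isolation(self, contrast_cohort, bundle):
        """Scaling the obesity->diabetes RR with diabetes incidence zeroed
        changes nothing: the parameter touches only the diabetes pathway."""
        import copy
        quiet = copy.deepcopy(bundle.background)
        quiet.incidence["diabetes"] = {"male": [0.0] * 12, "female": [0.0] * 12}
        quiet.__post_init__()
        b0 = ck.ParamBundle(bundle.progression, bundle.obesity, quiet,
                            bundle.simulation)
        b1 = ck.scale_param(b0, "rr_diabetes_obesity", 1.25)
        a = ck.simulate_cohort(contrast_cohort, b0, master_seed=6)
        b = ck.simulate_cohort(contrast_cohort, b1, master_seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_matched_seeds_trajectories_identical_for_never_diabetic(
            self, contrast_cohort, bundle):
        """Under matched per-person streams, persons who never acquire
        diabetes in either run have bit-identical eGFR trajectories when
        only the obesity->diabetes RR changes."""
        scaled = ck.scale_param(bundle, "rr_diabetes_obesity", 1.25)
        _, ta = ck.simulate_cohort(contrast_cohort.iloc[:200], bundle,
                                   master_seed=6, collect_trajectories=True)
        _, tb = ck.simulate_cohort(contrast_cohort.iloc[:200], scaled,
                                   master_seed=6, collect_trajectories=True)
        never_dia = set(ta.groupby("id")["diabetes"].max().pipe(
            lambda s: s[s == 0]).index) & set(
            tb.groupby("id")["diabetes"].max().pipe(lambda s: s[s == 0]).index)
        a = ta[ta["id"].isin(never_dia)].reset_index(drop=True)
        b = tb[tb["id"].isin(never_dia)].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestExchangeability:
    def test_null_effect_parameters_remove_bmi_dependence(self, bundle):
        """With every obesity RR set to 1 and the obesity slope coefficient
        zeroed, covariate-matched normal-weight and obesity groups have
        identical outcomes under matched seeds."""
        import copy
        obes = ck.ObesityParams.from_dict(bundle.obesity.to_dict(), [])
        for cat in ("overweight", "obesity"):
            for sex in ("male", "female"):
                obes.rr_diabetes[cat][sex] = 1.0
                obes.rr_hypertension[cat][sex] = 1.0
            obes.rr_mi[cat] = 1.0
            obes.rr_chd[cat] = 1.0
            obes.rr_stroke[cat] = 1.0
        prog = copy.deepcopy(bundle.progression)
        prog.coef_obesity = {"lt60": 0.0, "ge60": 0.0}
        null = ck.ParamBundle(prog, obes, bundle.background, bundle.simulation)

        spec = ck.default_cohort_spec(n=800, seed=41)
        base = ck.adjust_persistent_albuminuria(ck.generate_cohort(spec), 0.6, seed=42)
        lean = base.copy()
        lean["bmi"] = 22.0
        heavy = base.copy()
        heavy["bmi"] = 34.0
        ra = ck.simulate_cohort(lean, null, master_seed=11)
        rb = ck.simulate_cohort(heavy, null, master_seed=11)
        assert (ra["ever_ckd"] == rb["ever_ckd"]).all()
        assert (ra["highest_stage"] == rb["highest_stage"]).all()
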