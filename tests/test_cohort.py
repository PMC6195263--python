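"""Synthetic cohort generation, CKD-EPI, albuminuria adjustment, CSV I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ckdsim as ck
from ckdsim.cohort import CohortSchemaError, GENERATOR_AGE_BANDS
from ckdsim.types import BMI_CATEGORIES, RACES


@pytest.fixture(scope="module")
def big_cohort():
    return ck.generate_cohort(ck.default_cohort_spec(n=100_000, seed=7))


class TestGenerateCohort:
    def test_seeded_determinism(self):
        spec = ck.default_cohort_spec(n=2000, seed=7)
        a = ck.generate_cohort(spec)
        b = ck.generate_cohort(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_seed_changes_cohort(self):
        a = ck.generate_cohort(ck.default_cohort_spec(n=500, seed=1))
        b = ck.generate_cohort(ck.default_cohort_spec(n=500, seed=2))
        assert not a.equals(b)

    def test_single_person_cohort_is_valid(self, bundle):
        df = ck.generate_cohort(ck.default_cohort_spec(n=1, seed=3))
        assert len(df) == 1
        row = df.iloc[0]
        person = ck.PersonState(
            id=int(row["id"]), age=float(row["age"]), sex=row["sex"], race=row["race"],
            egfr=float(row["egfr"]), bmi=float(row["bmi"]), albuminuria=row["albuminuria"],
        )
        assert person.validate() == []

    def test_sex_split_recovery(self, big_cohort):
        # binomial 99% interval at n=100k around 0.52 is ~ +/- 0.004
        frac = (big_cohort["sex"] == "female").mean()
        assert frac == pytest.approx(0.52, abs=0.01)

    def test_marginals_match_spec(self, big_cohort):
        """Every configured marginal is recovered within a 99% multinomial
        interval at n=100,000."""
        spec = ck.default_cohort_spec()
        n = len(big_cohort)

        def check(observed, expected):
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < max(2.576 * se, 1e-4) * 1.5

        for race in RACES:
            check((big_cohort["race"] == race).mean(), spec.race_weights[race])
        age = big_cohort["age"]
        bands = [(age < 50), (age >= 50) & (age < 65), (age >= 65)]
        for band_mask, band in zip(bands, GENERATOR_AGE_BANDS):
            check(band_mask.mean(), spec.age_band_weights[band])
        cat = np.array(BMI_CATEGORIES, dtype=object)[
            np.digitize(big_cohort["bmi"], (18.5, 25, 30))]
        for bi, (band_mask, band) in enumerate(zip(bands, GENERATOR_AGE_BANDS)):
            for c in BMI_CATEGORIES:
                obs = (cat[band_mask.to_numpy()] == c).mean()
                exp = spec.bmi_cat_weights_by_age_band[band][c]
                se = np.sqrt(exp * (1 - exp) / band_mask.sum())
                assert abs(obs - exp) < max(2.576 * se, 1e-3) * 1.5

    def test_bmi_within_category_bounds(self, big_cohort):
        bmi = big_cohort["bmi"].to_numpy()
        assert bmi.min() >= 12.0 and bmi.max() <= 80.0

    def test_egfr_truncated_to_domain(self, big_cohort):
        egfr = big_cohort["egfr"].to_numpy()
        assert egfr.min() > 5.0 and egfr.max() <= 150.0

    def test_comorbidity_prevalence_rises_with_age(self, big_cohort):
        by_band = big_cohort.assign(old=big_cohort["age"] >= 65).groupby("old")
        prev = by_band[["diabetes", "hypertension"]].mean()
        assert (prev.loc[True] > prev.loc[False]).all()

    def test_degenerate_weights_rejected(self):
        spec = ck.default_cohort_spec()
        spec.race_weights = {r: 0.0 for r in RACES}
        with pytest.raises(CohortSchemaError, match="race_weights"):
            ck.generate_cohort(spec)

    def test_bmi_weights_do_not_perturb_other_columns(self):
        """Fixed per-attribute draw layout: changing only the BMI-category
        weights leaves every other column identical under the same seed."""
        normal = ck.default_cohort_spec(n=800, seed=55, bmi_cat_weights_by_age_band={
            b: {"underweight": 0, "normal": 1, "overweight": 0, "obesity": 0}
            for b in GENERATOR_AGE_BANDS})
        obese = ck.default_cohort_spec(n=800, seed=55, bmi_cat_weights_by_age_band={
            b: {"underweight": 0, "normal": 0, "overweight": 0, "obesity": 1}
            for b in GENERATOR_AGE_BANDS})
        a = ck.generate_cohort(normal)
        b = ck.generate_cohort(obese)
        for col in ("age", "sex", "race", "egfr"):
            assert (a[col] == b[col]).all()
        assert (a["bmi"] < 25).all() and (b["bmi"] >= 30).all()


class TestCkdEpi:
    # frozen against an independent evaluation of the published closed form
    @pytest.mark.parametrize(
        "scr, age, sex, race, expected",
        [
            (0.8, 50, "female", "nh_white", 85.96),
            (0.7, 20, "female", "nh_white", 124.72),  # knot: power terms collapse
            (1.2, 60, "male", "nh_black", 75.72),
            (0.5, 40, "male", "nh_white", 135.55),
        ],
    )
    def test_spot_values(self, scr, age, sex, race, expected):
        assert ck.ckd_epi_egfr(scr, age, sex, race) == pytest.approx(expected, abs=0.5)

    @given(
        scr1=st.floats(0.3, 5.0), bump=st.floats(0.01, 3.0),
        age=st.floats(18, 90), female=st.booleans(), black=st.booleans(),
    )
    def test_monotone_decreasing_in_creatinine(self, scr1, bump, age, female, black):
        sex = "female" if female else "male"
        race = "nh_black" if black else "nh_white"
        assert ck.ckd_epi_egfr(scr1 + bump, age, sex, race) <= ck.ckd_epi_egfr(
            scr1, age, sex, race)

    def test_nonpositive_creatinine_rejected(self):
        with pytest.raises(ValueError, match="creatinine"):
            ck.ckd_epi_egfr(0.0, 50, "male", "nh_white")

    @given(
        egfr=st.floats(6, 149), age=st.floats(18, 90),
        female=st.booleans(), black=st.booleans(),
    )
    def test_creatinine_inversion_round_trip(self, egfr, age, female, black):
        sex = "female" if female else "male"
        race = "nh_black" if black else "nh_white"
        scr = ck.scr_from_egfr(egfr, age, sex, race)
        assert ck.ckd_epi_egfr(scr, age, sex, race) == pytest.approx(egfr, rel=1e-9)


class TestAlbuminuriaAdjustment:
    def test_retain_prob_one_is_identity(self, small_cohort):
        out = ck.adjust_persistent_albuminuria(small_cohort, 1.0, seed=5)
        pd.testing.assert_frame_equal(out, small_cohort)

    def test_retain_prob_zero_clears_moderate(self, small_cohort):
        out = ck.adjust_persistent_albuminuria(small_cohort, 0.0, seed=5)
        assert (out["albuminuria"] != "moderate").all()
        # severe untouched
        assert (
            (out["albuminuria"] == "severe") == (small_cohort["albuminuria"] == "severe")
        ).all()

    def test_retention_fraction_binomial(self):
        df = pd.DataFrame({
            "id": np.arange(50_000),
            "albuminuria": ["moderate"] * 50_000,
        })
        out = ck.adjust_persistent_albuminuria(df, 0.6, seed=17)
        kept = (out["albuminuria"] == "moderate").sum()
        assert abs(kept - 30_000) < 330  # 99% binomial interval

    def test_bad_probability_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            ck.adjust_persistent_albuminuria(small_cohort, 1.5, seed=0)


class TestProteinuriaMapping:
    @pytest.mark.parametrize(
        "alb, expected", [("normal", "p1"), ("moderate", "p2"), ("severe", "p3")]
    )
    def test_default_mapping(self, alb, expected):
        assert ck.map_albuminuria_to_proteinuria(alb) == expected

    def test_p4_override(self):
        assert ck.map_albuminuria_to_proteinuria("severe", p4_fraction_severe=1.0) == "p4"
        assert ck.map_albuminuria_to_proteinuria("severe", 0.5, u=0.2) == "p4"
        assert ck.map_albuminuria_to_proteinuria("severe", 0.5, u=0.8) == "p3"

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            ck.map_albuminuria_to_proteinuria("borderline")


class TestCsvRoundTrip:
    def test_write_then_read_is_lossless(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        ck.write_cohort_csv(small_cohort, path)
        back = ck.read_cohort_csv(path)
        for col in small_cohort.columns:
            if small_cohort[col].dtype.kind == "f":
                np.testing.assert_allclose(back[col], small_cohort[col], rtol=1e-9)
            else:
                assert (back[col].to_numpy() == small_cohort[col].to_numpy()).all()

    def test_missing_column_named(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        small_cohort.drop(columns=["bmi"]).to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="'bmi'"):
            ck.read_cohort_csv(path)

    def test_unparseable_row_cited(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        df = small_cohort.copy().astype({"bmi": object})
        df.loc[df.index[2], "bmi"] = "abc"
        df.to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="row 3"):
            ck.read_cohort_csv(path)

    def test_egfr_derived_from_creatinine_when_absent(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        small_cohort.drop(columns=["egfr"]).to_csv(path, index=False)
        back = ck.read_cohort_csv(path)
        np.testing.assert_allclose(back["egfr"], small_cohort["egfr"], rtol=1e-6)
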