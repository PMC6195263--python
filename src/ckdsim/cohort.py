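"""Synthetic baseline cohort generation and baseline derivations.

This module stands in for the survey cohort the model is normally populated
with: it draws a US-adult-like joint distribution of age, sex,
race/ethnicity, BMI, eGFR, albuminuria, diabetes, hypertension, and CVD
history, with every marginal configurable through :class:`CohortSpec`.  It
also implements the two baseline derivations applied to real data: the 2009
CKD-EPI creatinine equation and the persistence adjustment for a single
survey measurement of moderately increased albuminuria.

The generator consumes a fixed number of random draws per attribute block
regardless of category outcomes, so two specs that differ only in (say) the
BMI-category weights produce cohorts that are identical in every other
column under the same seed.  Generation order: age band, age, sex, race,
BMI category, BMI, eGFR, diabetes, hypertension, CHD, stroke, MI,
albuminuria.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .types import ALBUMINURIA_LEVELS, BMI_CATEGORIES, RACES, SEXES

#: Column order of the cohort CSV interchange format.  Booleans are 0/1;
#: categorical encodings are the literal strings of the domain tuples.
COHORT_COLUMNS = (
    "id", "age", "sex", "race", "scr_mg_dl", "egfr", "albuminuria",
    "diabetes", "hypertension", "chd", "stroke", "mi", "bmi",
)

_BOOL_COLUMNS = ("diabetes", "hypertension", "chd", "stroke", "mi")

GENERATOR_AGE_BANDS = ("30-49", "50-64", "65-90")
_AGE_BOUNDS = {"30-49": (30, 49), "50-64": (50, 64), "65-90": (65, 89)}


class CohortSchemaError(ValueError):
    """A cohort table is missing or violates a documented column."""


@dataclass
class CohortSpec:
    """Configurable marginals of the synthetic baseline cohort."""

    n: int = 10000
    seed: int = 20100
    age_band_weights: dict = field(default_factory=dict)
    sex_split_female: float = 0.52
    race_weights: dict = field(default_factory=dict)
    bmi_cat_weights_by_age_band: dict = field(default_factory=dict)
    egfr_age_model: dict = field(default_factory=dict)
    obesity_bmi_scale: float = 4.5
    prevalence: dict = field(default_factory=dict)
    bmi_prevalence_multipliers: dict = field(default_factory=dict)
    albuminuria_retain_prob: float = 0.6
    proteinuria_p4_fraction_severe: float = 0.0

    def validate(self) -> list[str]:
        errs = []
        if self.n < 1:
            errs.append("cohort.n: must be >= 1")
        for name, weights, domain in (
            ("age_band_weights", self.age_band_weights, GENERATOR_AGE_BANDS),
            ("race_weights", self.race_weights, RACES),
        ):
            errs += _check_weights(f"cohort.{name}", weights, domain)
        for band in GENERATOR_AGE_BANDS:
            w = self.bmi_cat_weights_by_age_band.get(band)
            if w is None:
                errs.append(f"cohort.bmi_cat_weights_by_age_band.{band}: missing field")
            else:
                errs += _check_weights(
                    f"cohort.bmi_cat_weights_by_age_band.{band}", w, BMI_CATEGORIES
                )
        if not (0.0 <= self.sex_split_female <= 1.0):
            errs.append("cohort.sex_split_female: must be in [0, 1]")
        if not (0.0 <= self.albuminuria_retain_prob <= 1.0):
            errs.append("cohort.albuminuria_retain_prob: must be in [0, 1]")
        for key in ("intercept_age30", "slope_per_year", "sd"):
            if key not in self.egfr_age_model:
                errs.append(f"cohort.egfr_age_model.{key}: missing field")
        if self.egfr_age_model.get("sd", 1.0) <= 0:
            errs.append("cohort.egfr_age_model.sd: must be > 0")
        return errs

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        kwargs = {k: copy.deepcopy(v) for k, v in d.items()}
        spec = cls(**kwargs)
        errs = spec.validate()
        if errs:
            raise CohortSchemaError("; ".join(errs))
        return spec

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "age_band_weights": dict(self.age_band_weights),
            "sex_split_female": self.sex_split_female,
            "race_weights": dict(self.race_weights),
            "bmi_cat_weights_by_age_band": copy.deepcopy(self.bmi_cat_weights_by_age_band),
            "egfr_age_model": dict(self.egfr_age_model),
            "obesity_bmi_scale": self.obesity_bmi_scale,
            "prevalence": copy.deepcopy(self.prevalence),
            "bmi_prevalence_multipliers": copy.deepcopy(self.bmi_prevalence_multipliers),
            "albuminuria_retain_prob": self.albuminuria_retain_prob,
            "proteinuria_p4_fraction_severe": self.proteinuria_p4_fraction_severe,
        }


def _check_weights(name: str, weights: dict, domain) -> list[str]:
    errs = []
    missing = [k for k in domain if k not in weights]
    if missing:
        errs.append(f"{name}: missing categories {missing}")
        return errs
    total = sum(float(weights[k]) for k in domain)
    if any(float(weights[k]) < 0 for k in domain):
        errs.append(f"{name}: negative weight")
    if total <= 0:
        errs.append(f"{name}: weights are all zero")
    elif abs(total - 1.0) > 1e-9:
        errs.append(f"{name}: weights sum to {total}, expected 1")
    return errs


def default_cohort_spec(**overrides) -> CohortSpec:
    """Package-shipped cohort spec, optionally with field overrides."""
    text = resources.files("ckdsim").joinpath("data/default_cohort.yaml").read_text()
    d = yaml.safe_load(text)
    d.update(overrides)
    return CohortSpec.from_dict(d)


def load_cohort_spec(path, **overrides) -> CohortSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d.update(overrides)
    return CohortSpec.from_dict(d)


# ---------------------------------------------------------------------------
# CKD-EPI 2009 creatinine equation

_KAPPA = {"male": 0.9, "female": 0.7}
_ALPHA = {"male": -0.411, "female": -0.329}


def ckd_epi_egfr(scr, age, sex, race):
    """eGFR (ml/min/1.73m²) from serum creatinine via the 2009 CKD-EPI
    creatinine equation.

    eGFR = 141 × min(Scr/κ, 1)^α × max(Scr/κ, 1)^−1.209 × 0.993^age
           × 1.018 [female] × 1.159 [Black]

    with κ = 0.7 (F) / 0.9 (M) and α = −0.329 (F) / −0.411 (M).  Accepts
    scalars or arrays; sex/race as domain strings (race term applies to
    ``nh_black``).
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be > 0 mg/dL")
    female = np.asarray(sex) == "female"
    black = np.asarray(race) == "nh_black"
    kappa = np.where(female, _KAPPA["female"], _KAPPA["male"])
    alpha = np.where(female, _ALPHA["female"], _ALPHA["male"])
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
        * np.where(female, 1.018, 1.0)
        * np.where(black, 1.159, 1.0)
    )
    return float(egfr) if egfr.ndim == 0 else egfr


def scr_from_egfr(egfr, age, sex, race):
    """Invert the CKD-EPI equation: serum creatinine (mg/dL) from eGFR.

    The equation is strictly decreasing in creatinine, so the inverse is the
    closed-form piecewise power law around the sex-specific knot κ.
    """
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(egfr <= 0):
        raise ValueError("eGFR must be > 0")
    female = np.asarray(sex) == "female"
    black = np.asarray(race) == "nh_black"
    kappa = np.where(female, _KAPPA["female"], _KAPPA["male"])
    alpha = np.where(female, _ALPHA["female"], _ALPHA["male"])
    knot = (  # eGFR at scr == kappa
        141.0 * 0.993 ** age * np.where(female, 1.018, 1.0) * np.where(black, 1.159, 1.0)
    )
    ratio = np.where(
        egfr <= knot,
        (egfr / knot) ** (-1.0 / 1.209),  # scr >= kappa branch
        (egfr / knot) ** (1.0 / alpha),   # scr < kappa branch
    )
    scr = kappa * ratio
    return float(scr) if scr.ndim == 0 else scr


# ---------------------------------------------------------------------------
# Generation

def _pick(u: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Categorical draw from one uniform per person via cumulative weights."""
    cum = np.cumsum(weights) / np.sum(weights)
    return np.searchsorted(cum, u, side="right").clip(0, len(weights) - 1)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a baseline cohort of ``spec.n`` persons.

    Returns a DataFrame in the cohort CSV schema (:data:`COHORT_COLUMNS`)
    with ids 0..n−1.  Bit-for-bit reproducible from (spec, spec.seed).
    Albuminuria is emitted as observed (single-measurement); apply
    :func:`adjust_persistent_albuminuria` to obtain persistent status.
    """
    errs = spec.validate()
    if errs:
        raise CohortSchemaError("; ".join(errs))
    n = spec.n
    rng = np.random.default_rng(spec.seed)

    band_w = np.array([spec.age_band_weights[b] for b in GENERATOR_AGE_BANDS], float)
    band = _pick(rng.random(n), band_w)
    lo = np.array([_AGE_BOUNDS[b][0] for b in GENERATOR_AGE_BANDS])[band]
    hi = np.array([_AGE_BOUNDS[b][1] for b in GENERATOR_AGE_BANDS])[band]
    age = lo + np.floor(rng.random(n) * (hi - lo + 1)).astype(int)

    female = rng.random(n) < spec.sex_split_female
    sex = np.where(female, "female", "male")

    race_w = np.array([spec.race_weights[r] for r in RACES], float)
    race_idx = _pick(rng.random(n), race_w)
    race = np.array(RACES, dtype=object)[race_idx]

    bmi_w = np.array(
        [[spec.bmi_cat_weights_by_age_band[b][c] for c in BMI_CATEGORIES]
         for b in GENERATOR_AGE_BANDS], float
    )
    u_cat = rng.random(n)
    bmi_cat_idx = np.empty(n, dtype=int)
    for bi in range(len(GENERATOR_AGE_BANDS)):
        m = band == bi
        bmi_cat_idx[m] = _pick(u_cat[m], bmi_w[bi])

    # one uniform per person, transformed within the drawn category
    u_bmi = rng.random(n)
    bmi = np.empty(n, dtype=float)
    for ci, cat in enumerate(BMI_CATEGORIES):
        m = bmi_cat_idx == ci
        u = u_bmi[m]
        if cat == "underweight":
            bmi[m] = 16.0 + u * 2.4
        elif cat == "normal":
            bmi[m] = 18.5 + u * 6.4
        elif cat == "overweight":
            bmi[m] = 25.0 + u * 4.9
        else:  # exponential tail above 30, clipped to the BMI domain
            bmi[m] = np.minimum(
                30.0 - spec.obesity_bmi_scale * np.log1p(-u * (1 - 1e-12)), 75.0
            )

    em = spec.egfr_age_model
    loc = em["intercept_age30"] + em["slope_per_year"] * (age - 30.0)
    sd = em["sd"]
    a, b = (5.0 - loc) / sd, (150.0 - loc) / sd
    egfr = stats.truncnorm.ppf(rng.random(n), a, b, loc=loc, scale=sd)
    egfr = np.clip(egfr, 5.0 + 1e-9, 150.0)

    def prev(cond: str, mult_group: str) -> np.ndarray:
        base = np.array([spec.prevalence[cond][b] for b in GENERATOR_AGE_BANDS])[band]
        mult = np.array(
            [spec.bmi_prevalence_multipliers[mult_group][c] for c in BMI_CATEGORIES]
        )[bmi_cat_idx]
        return np.clip(base * mult, 0.0, 1.0)

    diabetes = rng.random(n) < prev("diabetes", "diabetes")
    hypertension = rng.random(n) < prev("hypertension", "hypertension")
    chd = rng.random(n) < prev("chd", "cvd")
    stroke = rng.random(n) < prev("stroke", "cvd")
    mi = rng.random(n) < prev("mi", "cvd")

    p_sev = prev("alb_severe", "albuminuria")
    p_mod = prev("alb_moderate", "albuminuria")
    u_alb = rng.random(n)
    albuminuria = np.where(
        u_alb < p_sev, "severe", np.where(u_alb < p_sev + p_mod, "moderate", "normal")
    )

    df = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "age": age,
            "sex": sex,
            "race": race,
            "scr_mg_dl": scr_from_egfr(egfr, age, sex, race),
            "egfr": egfr,
            "albuminuria": albuminuria,
            "diabetes": diabetes.astype(int),
            "hypertension": hypertension.astype(int),
            "chd": chd.astype(int),
            "stroke": stroke.astype(int),
            "mi": mi.astype(int),
            "bmi": bmi,
        }
    )
    return df


def adjust_persistent_albuminuria(cohort: pd.DataFrame, retain_prob: float,
                                  seed: int) -> pd.DataFrame:
    """Persistence adjustment for single-measurement albuminuria.

    Each person observed with moderately increased albuminuria independently
    retains it with probability ``retain_prob``; otherwise they are reset to
    normal.  Severe and normal are untouched.  Returns a new DataFrame.
    """
    if not (0.0 <= retain_prob <= 1.0):
        raise ValueError("retain_prob must be in [0, 1]")
    out = cohort.copy()
    u = np.random.default_rng(seed).random(len(out))
    moderate = out["albuminuria"].to_numpy() == "moderate"
    reset = moderate & (u >= retain_prob)
    out.loc[reset, "albuminuria"] = "normal"
    return out


_DEFAULT_PROT_MAP = {"normal": "p1", "moderate": "p2", "severe": "p3"}


def map_albuminuria_to_proteinuria(albuminuria: str, p4_fraction_severe: float = 0.0,
                                   u: float | None = None) -> str:
    """Bridge albuminuria categories to the 24-hour proteinuria covariate.

    Default mapping: normal→p1 (<0.10 g/24h), moderate→p2 (0.10–0.49),
    severe→p3 (0.50–1.49).  A configurable fraction of severe cases can be
    assigned to p4 (≥1.50); ``u`` supplies the uniform deciding the
    assignment (required only when the fraction is positive).
    """
    if albuminuria not in ALBUMINURIA_LEVELS:
        raise ValueError(f"unknown albuminuria category {albuminuria!r}")
    if albuminuria == "severe" and p4_fraction_severe > 0:
        if p4_fraction_severe >= 1.0:
            return "p4"
        if u is None:
            raise ValueError("p4 assignment requires a uniform draw u")
        return "p4" if u < p4_fraction_severe else "p3"
    return _DEFAULT_PROT_MAP[albuminuria]


# ---------------------------------------------------------------------------
# CSV I/O

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    out = cohort.loc[:, list(COHORT_COLUMNS)].copy()
    out.to_csv(path, index=False, float_format="%.10g")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    ``scr_mg_dl`` is optional when ``egfr`` is present and vice versa; a
    missing eGFR column is derived through the CKD-EPI equation.  Raises
    :class:`CohortSchemaError` naming the offending column, or a parse error
    citing the 1-based data row for unparseable numeric values.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in COHORT_COLUMNS if c not in ("scr_mg_dl", "egfr")]
    for col in required:
        if col not in df.columns:
            raise CohortSchemaError(f"cohort file is missing required column '{col}'")
    if "egfr" not in df.columns and "scr_mg_dl" not in df.columns:
        raise CohortSchemaError("cohort file needs an 'egfr' or 'scr_mg_dl' column")

    out = pd.DataFrame()
    numeric = ["id", "age", "bmi"] + [c for c in ("scr_mg_dl", "egfr") if c in df.columns]
    for col in numeric + list(_BOOL_COLUMNS):
        vals = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        raw_nonempty = df[col].to_numpy() != ""
        bad = vals.isna().to_numpy() & raw_nonempty
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise CohortSchemaError(
                f"unparseable value {df[col].iloc[row - 1]!r} in column '{col}', data row {row}"
            )
        if col in ("scr_mg_dl", "egfr"):
            out[col] = vals
        elif col in _BOOL_COLUMNS:
            out[col] = vals.fillna(0).astype(int)
        else:
            if vals.isna().any():
                row = int(np.flatnonzero(vals.isna())[0]) + 1
                raise CohortSchemaError(f"missing value in column '{col}', data row {row}")
            out[col] = vals
    out["id"] = out["id"].astype(np.int64)
    out["age"] = out["age"].astype(float)

    for col, domain in (("sex", SEXES), ("race", RACES), ("albuminuria", ALBUMINURIA_LEVELS)):
        vals = df[col].to_numpy()
        bad = ~np.isin(vals, domain)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise CohortSchemaError(
                f"invalid {col} value {vals[bad][0]!r} in data row {row}"
            )
        out[col] = vals

    if "egfr" not in out.columns or out["egfr"].isna().all():
        out["egfr"] = ckd_epi_egfr(
            out["scr_mg_dl"].to_numpy(), out["age"].to_numpy(),
            out["sex"].to_numpy(), out["race"].to_numpy(),
        )
    elif out["egfr"].isna().any():
        m = out["egfr"].isna()
        out.loc[m, "egfr"] = ckd_epi_egfr(
            out.loc[m, "scr_mg_dl"].to_numpy(), out.loc[m, "age"].to_numpy(),
            out.loc[m, "sex"].to_numpy(), out.loc[m, "race"].to_numpy(),
        )
    if "scr_mg_dl" not in out.columns:
        out["scr_mg_dl"] = scr_from_egfr(
            out["egfr"].to_numpy(), out["age"].to_numpy(),
            out["sex"].to_numpy(), out["race"].to_numpy(),
        )
    if out["id"].duplicated().any():
        raise CohortSchemaError("cohort ids must be unique")
    return out.loc[:, list(COHORT_COLUMNS)]
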