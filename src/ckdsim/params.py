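"""Model parameters: slope coefficients, obesity relative risks, background
rates, and simulation configuration.

The slope parameters are the published mixed-effect coefficients for annual
eGFR change, estimated separately for persons with baseline eGFR < 60 and
≥ 60 ml/min/1.73m².  Obesity parameters are published cohort-study relative
risks for diabetes/hypertension/CVD plus literature values for annual BMI
drift by age/race/sex.  Background incidence and mortality tables are package-shipped,
non-authoritative stand-ins (see docs/methods.md) and are ordinary
configuration: every value can be replaced through the YAML bundle.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .types import BMI_DELTA_AGE_BANDS, EGFR_BANDS, SEXES, STAGE_LABELS

#: Events with an annual background incidence table.
BACKGROUND_EVENTS = (
    "diabetes",
    "hypertension",
    "chd",
    "stroke",
    "mi",
    "albuminuria",        # normal -> moderately increased
    "albuminuria_severe",  # moderate -> severely increased
)

#: Progression coefficient names (each a map egfr_band -> ml/min/1.73m²/yr).
PROGRESSION_COEFS = (
    "coef_female",
    "coef_nh_black",
    "coef_hispanic",
    "coef_other",
    "coef_prot_p2",
    "coef_prot_p3",
    "coef_prot_p4",
    "coef_diabetes",
    "coef_hypertension",
    "coef_obesity",
)


class ParameterValidationError(ValueError):
    """Aggregates every validation failure in a parameter bundle."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid parameter bundle:\n" + "\n".join(f"  - {e}" for e in self.errors)
        )


def _need_band_map(d: dict, key: str, errors: list[str]) -> dict:
    val = d.get(key)
    if val is None:
        errors.append(f"progression.{key}: missing field")
        return {b: 0.0 for b in EGFR_BANDS}
    out = {}
    for b in EGFR_BANDS:
        if b not in val:
            errors.append(f"progression.{key}.{b}: missing field")
            out[b] = 0.0
        else:
            out[b] = float(val[b])
    return out


@dataclass
class ProgressionParams:
    """Annual eGFR change model: base + covariate shifts + residual SD.

    ``variance_multiplier_ge60`` is the calibration factor shrinking the
    variance of the annual-change distribution for the baseline-eGFR ≥ 60
    stratum (applied as sd × sqrt(multiplier)).  The published model derives
    it from an external cohort; here it ships as a configurable default and
    is NOT anchored to a published number.
    """

    base_change: dict
    coef_female: dict
    coef_nh_black: dict
    coef_hispanic: dict
    coef_other: dict
    coef_prot_p2: dict
    coef_prot_p3: dict
    coef_prot_p4: dict
    coef_diabetes: dict
    coef_hypertension: dict
    coef_obesity: dict
    sd_annual_change: dict
    variance_multiplier_ge60: float = 0.5

    def effective_sd(self, band: str) -> float:
        """Residual SD of annual eGFR change for a baseline band."""
        sd = self.sd_annual_change[band]
        if band == "ge60":
            sd *= math.sqrt(self.variance_multiplier_ge60)
        return sd

    def validate(self) -> list[str]:
        errs = []
        for b in EGFR_BANDS:
            if self.sd_annual_change.get(b, -1.0) <= 0:
                errs.append(f"progression.sd_annual_change.{b}: must be > 0")
        if not (0.0 < self.variance_multiplier_ge60 <= 1.0):
            errs.append("progression.variance_multiplier_ge60: must be in (0, 1]")
        return errs

    @classmethod
    def from_dict(cls, d: dict, errors: list[str]) -> "ProgressionParams":
        fields = {"base_change": _need_band_map(d, "base_change", errors)}
        for name in PROGRESSION_COEFS:
            fields[name] = _need_band_map(d, name, errors)
        fields["sd_annual_change"] = _need_band_map(d, "sd_annual_change", errors)
        fields["variance_multiplier_ge60"] = float(d.get("variance_multiplier_ge60", 0.5))
        return cls(**fields)

    def to_dict(self) -> dict:
        d = {"base_change": dict(self.base_change)}
        for name in PROGRESSION_COEFS:
            d[name] = dict(getattr(self, name))
        d["sd_annual_change"] = dict(self.sd_annual_change)
        d["variance_multiplier_ge60"] = self.variance_multiplier_ge60
        return d


@dataclass
class ObesityParams:
    """Relative risks by BMI category and annual BMI drift.

    ``rr_diabetes`` / ``rr_hypertension`` are keyed [bmi_cat][sex] for
    overweight and obesity; ``rr_mi`` / ``rr_chd`` / ``rr_stroke`` are
    sex-invariant, keyed [bmi_cat].  Underweight and normal weight carry
    RR = 1 everywhere.  ``bmi_delta`` is keyed [age_band][race_group][sex]
    with race_group in {white, black}; ``race_to_bmi_group`` maps the four
    cohort race groups onto those two (hispanic/other default to white).
    """

    rr_diabetes: dict
    rr_hypertension: dict
    rr_mi: dict
    rr_chd: dict
    rr_stroke: dict
    bmi_delta: dict
    race_to_bmi_group: dict = field(
        default_factory=lambda: {
            "nh_white": "white",
            "nh_black": "black",
            "hispanic": "white",
            "other": "white",
        }
    )

    def rr(self, event: str, bmi_cat: str, sex: str) -> float:
        """Relative risk for an incident event given current BMI category."""
        if bmi_cat in ("underweight", "normal"):
            return 1.0
        if event == "diabetes":
            return self.rr_diabetes[bmi_cat][sex]
        if event == "hypertension":
            return self.rr_hypertension[bmi_cat][sex]
        if event == "mi":
            return self.rr_mi[bmi_cat]
        if event == "chd":
            return self.rr_chd[bmi_cat]
        if event == "stroke":
            return self.rr_stroke[bmi_cat]
        return 1.0

    def annual_bmi_change(self, age: float, race: str, sex: str) -> float:
        band = "30-49" if age < 50 else "50+"
        group = self.race_to_bmi_group[race]
        return self.bmi_delta[band][group][sex]

    def validate(self) -> list[str]:
        errs = []
        for name in ("rr_diabetes", "rr_hypertension"):
            table = getattr(self, name)
            for cat in ("overweight", "obesity"):
                for sex in SEXES:
                    v = table.get(cat, {}).get(sex)
                    if v is None:
                        errs.append(f"obesity.{name}.{cat}.{sex}: missing field")
                    elif v < 0:
                        errs.append(f"obesity.{name}.{cat}.{sex}: relative risk must be >= 0")
        for name in ("rr_mi", "rr_chd", "rr_stroke"):
            table = getattr(self, name)
            for cat in ("overweight", "obesity"):
                v = table.get(cat)
                if v is None:
                    errs.append(f"obesity.{name}.{cat}: missing field")
                elif v < 0:
                    errs.append(f"obesity.{name}.{cat}: relative risk must be >= 0")
        for band in BMI_DELTA_AGE_BANDS:
            for group in ("white", "black"):
                for sex in SEXES:
                    v = self.bmi_delta.get(band, {}).get(group, {}).get(sex)
                    if v is None:
                        errs.append(f"obesity.bmi_delta.{band}.{group}.{sex}: missing field")
                    elif not math.isfinite(v):
                        errs.append(f"obesity.bmi_delta.{band}.{group}.{sex}: must be finite")
        return errs

    @classmethod
    def from_dict(cls, d: dict, errors: list[str]) -> "ObesityParams":
        kwargs = {}
        for name in ("rr_diabetes", "rr_hypertension", "rr_mi", "rr_chd", "rr_stroke",
                     "bmi_delta"):
            if name not in d:
                errors.append(f"obesity.{name}: missing field")
                kwargs[name] = {}
            else:
                kwargs[name] = copy.deepcopy(d[name])
        if "race_to_bmi_group" in d:
            kwargs["race_to_bmi_group"] = dict(d["race_to_bmi_group"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "rr_diabetes": copy.deepcopy(self.rr_diabetes),
            "rr_hypertension": copy.deepcopy(self.rr_hypertension),
            "rr_mi": dict(self.rr_mi),
            "rr_chd": dict(self.rr_chd),
            "rr_stroke": dict(self.rr_stroke),
            "bmi_delta": copy.deepcopy(self.bmi_delta),
            "race_to_bmi_group": dict(self.race_to_bmi_group),
        }


@dataclass
class BackgroundRates:
    """Annual background probabilities by age band and sex.

    Stored compactly as band edges plus one probability vector per sex per
    series; exposed as tidy tables (age_lo, age_hi, sex, annual_prob) through
    :meth:`table`.  Mortality is all-cause and is multiplied by a
    stage-specific hazard ratio and a CVD hazard ratio in the engine.
    Albuminuria incidence (normal→moderate) is additionally multiplied by
    configurable factors when diabetes or hypertension is present.
    """

    age_edges: list          # ascending band lower edges plus final upper edge
    mortality: dict          # sex -> list of annual probabilities per band
    incidence: dict          # event -> sex -> list of probabilities per band
    hr_mortality_by_stage: dict
    hr_mortality_cvd: float = 1.6
    albuminuria_rr_diabetes: float = 3.0
    albuminuria_rr_hypertension: float = 1.5

    def __post_init__(self) -> None:
        self._edges = np.asarray(self.age_edges, dtype=float)
        self._mort = {s: np.asarray(self.mortality[s], dtype=float) for s in self.mortality}
        self._inc = {
            ev: {s: np.asarray(t[s], dtype=float) for s in t}
            for ev, t in self.incidence.items()
        }

    def _band_index(self, age):
        idx = np.searchsorted(self._edges, np.asarray(age, dtype=float), side="right") - 1
        return np.clip(idx, 0, len(self._edges) - 2)

    def annual_prob(self, event: str, age, female) -> np.ndarray:
        """Vectorized background incidence lookup for one event series."""
        idx = self._band_index(age)
        f = np.asarray(female, dtype=bool)
        return np.where(f, self._inc[event]["female"][idx], self._inc[event]["male"][idx])

    def mortality_prob(self, age, female) -> np.ndarray:
        idx = self._band_index(age)
        f = np.asarray(female, dtype=bool)
        return np.where(f, self._mort["female"][idx], self._mort["male"][idx])

    def table(self, event: str | None = None) -> pd.DataFrame:
        """Tidy table (age_lo, age_hi, sex, annual_prob) for one series."""
        src = self._mort if event is None else self._inc[event]
        rows = []
        for sex in SEXES:
            for i in range(len(self._edges) - 1):
                rows.append(
                    {
                        "age_lo": self._edges[i],
                        "age_hi": self._edges[i + 1],
                        "sex": sex,
                        "annual_prob": src[sex][i],
                    }
                )
        return pd.DataFrame(rows)

    def validate(self) -> list[str]:
        errs = []
        nb = len(self._edges) - 1
        if nb < 1 or np.any(np.diff(self._edges) <= 0):
            errs.append("background.age_bands: edges must be strictly increasing")
        series = [("mortality", self._mort)] + [
            (f"incidence.{ev}", t) for ev, t in self._inc.items()
        ]
        for name, table in series:
            for sex in SEXES:
                if sex not in table:
                    errs.append(f"background.{name}.{sex}: missing field")
                    continue
                v = table[sex]
                if len(v) != nb:
                    errs.append(f"background.{name}.{sex}: expected {nb} values, got {len(v)}")
                    continue
                if np.any((v < 0) | (v > 1)):
                    errs.append(f"background.{name}.{sex}: probabilities must be in [0, 1]")
                if np.any(np.diff(v) < 0):
                    errs.append(f"background.{name}.{sex}: must be non-decreasing in age")
        for ev in BACKGROUND_EVENTS:
            if ev not in self._inc:
                errs.append(f"background.incidence.{ev}: missing field")
        for lab in STAGE_LABELS:
            hr = self.hr_mortality_by_stage.get(lab)
            if hr is None:
                errs.append(f"background.hr_mortality_by_stage.{lab}: missing field")
            elif hr <= 0:
                errs.append(f"background.hr_mortality_by_stage.{lab}: must be > 0")
        if self.hr_mortality_cvd <= 0:
            errs.append("background.hr_mortality_cvd: must be > 0")
        for name in ("albuminuria_rr_diabetes", "albuminuria_rr_hypertension"):
            if getattr(self, name) < 0:
                errs.append(f"background.{name}: must be >= 0")
        return errs

    @classmethod
    def from_dict(cls, d: dict, errors: list[str]) -> "BackgroundRates":
        for key in ("age_bands", "mortality", "incidence", "hr_mortality_by_stage"):
            if key not in d:
                errors.append(f"background.{key}: missing field")
        return cls(
            age_edges=list(d.get("age_bands", [30, 90])),
            mortality=copy.deepcopy(d.get("mortality", {s: [0.0] for s in SEXES})),
            incidence=copy.deepcopy(
                d.get("incidence", {ev: {s: [0.0] for s in SEXES} for ev in BACKGROUND_EVENTS})
            ),
            hr_mortality_by_stage=dict(
                d.get("hr_mortality_by_stage", {lab: 1.0 for lab in STAGE_LABELS})
            ),
            hr_mortality_cvd=float(d.get("hr_mortality_cvd", 1.0)),
            albuminuria_rr_diabetes=float(d.get("albuminuria_rr_diabetes", 1.0)),
            albuminuria_rr_hypertension=float(d.get("albuminuria_rr_hypertension", 1.0)),
        )

    def to_dict(self) -> dict:
        return {
            "age_bands": [float(x) for x in self.age_edges],
            "mortality": {s: [float(x) for x in self.mortality[s]] for s in self.mortality},
            "incidence": {
                ev: {s: [float(x) for x in t[s]] for s in t}
                for ev, t in self.incidence.items()
            },
            "hr_mortality_by_stage": {k: float(v) for k, v in self.hr_mortality_by_stage.items()},
            "hr_mortality_cvd": self.hr_mortality_cvd,
            "albuminuria_rr_diabetes": self.albuminuria_rr_diabetes,
            "albuminuria_rr_hypertension": self.albuminuria_rr_hypertension,
        }

    @classmethod
    def flat(cls, incidence: float = 0.0, mortality: float = 0.0,
             stage_hr: float = 1.0, cvd_hr: float = 1.0) -> "BackgroundRates":
        """Single-band constant-rate tables; handy for controlled experiments."""
        return cls(
            age_edges=[30.0, 200.0],
            mortality={s: [mortality] for s in SEXES},
            incidence={ev: {s: [incidence] for s in SEXES} for ev in BACKGROUND_EVENTS},
            hr_mortality_by_stage={lab: stage_hr for lab in STAGE_LABELS},
            hr_mortality_cvd=cvd_hr,
            albuminuria_rr_diabetes=1.0,
            albuminuria_rr_hypertension=1.0,
        )


@dataclass
class SimulationConfig:
    """Run-level settings (horizon, seeds, bootstrap, engine switches)."""

    start_year: int = 2010
    max_age: int = 90
    bootstrap_reps: int = 100
    ci_percentiles: tuple = (2.5, 97.5)
    master_seed: int = 20181019
    deterministic_mode: bool = False
    slope_redraw_policy: str = "once_at_baseline"
    pass_through_staging: bool = True

    def validate(self) -> list[str]:
        errs = []
        if self.bootstrap_reps < 1:
            errs.append("simulation.bootstrap_reps: must be >= 1")
        if self.max_age > 90:
            errs.append("simulation.max_age: must be <= 90")
        if self.slope_redraw_policy not in ("once_at_baseline", "annual_iid"):
            errs.append(
                "simulation.slope_redraw_policy: must be 'once_at_baseline' or 'annual_iid'"
            )
        if len(self.ci_percentiles) != 2 or not (
            0 <= self.ci_percentiles[0] < self.ci_percentiles[1] <= 100
        ):
            errs.append("simulation.ci_percentiles: must be an increasing pair in [0, 100]")
        return errs

    @classmethod
    def from_dict(cls, d: dict, errors: list[str]) -> "SimulationConfig":
        kwargs = {}
        for f in ("start_year", "max_age", "bootstrap_reps", "master_seed"):
            if f in d:
                kwargs[f] = int(d[f])
        if "ci_percentiles" in d:
            kwargs["ci_percentiles"] = tuple(float(x) for x in d["ci_percentiles"])
        for f in ("deterministic_mode", "pass_through_staging"):
            if f in d:
                kwargs[f] = bool(d[f])
        if "slope_redraw_policy" in d:
            kwargs["slope_redraw_policy"] = str(d["slope_redraw_policy"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "start_year": self.start_year,
            "max_age": self.max_age,
            "bootstrap_reps": self.bootstrap_reps,
            "ci_percentiles": list(self.ci_percentiles),
            "master_seed": self.master_seed,
            "deterministic_mode": self.deterministic_mode,
            "slope_redraw_policy": self.slope_redraw_policy,
            "pass_through_staging": self.pass_through_staging,
        }


class ParamBundle(NamedTuple):
    progression: ProgressionParams
    obesity: ObesityParams
    background: BackgroundRates
    simulation: SimulationConfig


def _bundle_from_dict(doc: dict) -> ParamBundle:
    errors: list[str] = []
    for section in ("progression", "obesity", "background", "simulation"):
        if section not in doc:
            errors.append(f"{section}: missing section")
    prog = ProgressionParams.from_dict(doc.get("progression", {}), errors)
    obes = ObesityParams.from_dict(doc.get("obesity", {}), errors)
    back = BackgroundRates.from_dict(doc.get("background", {}), errors)
    sim = SimulationConfig.from_dict(doc.get("simulation", {}), errors)
    errors += prog.validate() + obes.validate() + back.validate() + sim.validate()
    if errors:
        raise ParameterValidationError(errors)
    return ParamBundle(prog, obes, back, sim)


def load_params(path=None) -> ParamBundle:
    """Load and validate a parameter bundle from YAML.

    With ``path=None`` the package-shipped defaults are loaded.  All
    validation failures across all sections are aggregated into a single
    :class:`ParameterValidationError`.
    """
    if path is None:
        text = resources.files("ckdsim").joinpath("data/default_params.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ParameterValidationError(["parameter file is not a mapping"])
    return _bundle_from_dict(doc)


def save_params(bundle: ParamBundle, path) -> None:
    """Serialize a bundle to YAML (round-trips field-for-field)."""
    doc = {
        "progression": bundle.progression.to_dict(),
        "obesity": bundle.obesity.to_dict(),
        "background": bundle.background.to_dict(),
        "simulation": bundle.simulation.to_dict(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


#: Parameter names recognised by the one-way sensitivity machinery.
SCALABLE_PARAMS = ("rr_diabetes_obesity", "rr_hypertension_obesity", "coef_obesity")


def scale_param(bundle: ParamBundle, target: str, factor: float) -> ParamBundle:
    """Return a deep copy of *bundle* with one named parameter scaled.

    Targets: ``rr_diabetes_obesity`` and ``rr_hypertension_obesity`` scale the
    obesity-row relative risks for both sexes; ``coef_obesity`` scales the
    obesity slope coefficient in both baseline eGFR bands.  The input bundle
    is never modified.
    """
    if target not in SCALABLE_PARAMS:
        raise ValueError(
            f"unknown sensitivity target {target!r}; valid targets: {', '.join(SCALABLE_PARAMS)}"
        )
    if not factor > 0:
        raise ValueError("scale factor must be > 0")
    prog = copy.deepcopy(bundle.progression)
    obes = copy.deepcopy(bundle.obesity)
    if target == "rr_diabetes_obesity":
        for sex in SEXES:
            obes.rr_diabetes["obesity"][sex] *= factor
    elif target == "rr_hypertension_obesity":
        for sex in SEXES:
            obes.rr_hypertension["obesity"][sex] *= factor
    else:
        for band in EGFR_BANDS:
            prog.coef_obesity[band] *= factor
    return ParamBundle(prog, obes, copy.deepcopy(bundle.background),
                       copy.deepcopy(bundle.simulation))
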