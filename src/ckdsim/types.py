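"""Shared domain types for the CKD lifetime-risk microsimulation.

The model follows one person per year from a baseline age (30–90) until death
or age 90.  Kidney function is tracked as eGFR (ml/min/1.73m²); kidney damage
as an albuminuria category (urinary albumin-to-creatinine ratio: normal,
moderately increased ≥30 mg/g, severely increased >300 mg/g).  CKD stages are
the standard KDIGO bands, with stage 3 split into 3a/3b and stages 1–2
additionally requiring kidney damage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

SEXES = ("male", "female")
RACES = ("nh_white", "nh_black", "hispanic", "other")
ALBUMINURIA_LEVELS = ("normal", "moderate", "severe")
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obesity")
PROTEINURIA_CATEGORIES = ("p1", "p2", "p3", "p4")
EGFR_BANDS = ("lt60", "ge60")

#: BMI category cutoffs (kg/m²): <18.5 underweight, 18.5–24.9 normal,
#: 25–29.9 overweight, ≥30 obesity.
BMI_CUTOFFS = (18.5, 25.0, 30.0)

#: Baseline age bands used for reporting lifetime risk.
BASELINE_AGE_BANDS = ("30-49", "50-64", "65+")

#: Age bands for the annual BMI drift parameters.
BMI_DELTA_AGE_BANDS = ("30-49", "50+")


class Stage(enum.IntEnum):
    """CKD stage, ordered so that ``max`` gives the more advanced stage."""

    NONE = 0
    S1 = 1
    S2 = 2
    S3A = 3
    S3B = 4
    S4 = 5
    S5 = 6

    @property
    def label(self) -> str:
        return _STAGE_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "Stage":
        try:
            return _STAGE_FROM_LABEL[label]
        except KeyError:
            raise ValueError(f"unknown stage label {label!r}") from None


_STAGE_LABELS = {
    Stage.NONE: "none",
    Stage.S1: "s1",
    Stage.S2: "s2",
    Stage.S3A: "s3a",
    Stage.S3B: "s3b",
    Stage.S4: "s4",
    Stage.S5: "s5",
}
_STAGE_FROM_LABEL = {v: k for k, v in _STAGE_LABELS.items()}

STAGE_LABELS = tuple(_STAGE_LABELS[s] for s in Stage)
CKD_STAGE_LABELS = STAGE_LABELS[1:]  # s1..s5


def bmi_category(bmi: float) -> str:
    """BMI category from continuous BMI (kg/m²)."""
    if bmi < BMI_CUTOFFS[0]:
        return "underweight"
    if bmi < BMI_CUTOFFS[1]:
        return "normal"
    if bmi < BMI_CUTOFFS[2]:
        return "overweight"
    return "obesity"


def baseline_age_band(age: float) -> str:
    """Reporting age band at baseline: 30-49, 50-64, 65+."""
    if age < 50:
        return "30-49"
    if age < 65:
        return "50-64"
    return "65+"


def egfr_band(egfr: float) -> str:
    """Baseline eGFR stratum selecting the slope parameter column."""
    return "lt60" if egfr < 60 else "ge60"


@dataclass
class PersonState:
    """One simulated individual's current attributes.

    ``baseline_egfr_band`` is frozen at simulation start and never changes,
    mirroring the stratified estimation of the slope model.  ``person_slope``
    holds the individual's random slope deviation draw (ml/min/1.73m²/yr)
    around the covariate mean; the covariate part is recomputed every cycle.
    """

    id: int
    age: float
    sex: str
    race: str
    egfr: float
    bmi: float
    alive: bool = True
    albuminuria: str = "normal"
    proteinuria_cat: str = "p1"
    diabetes: bool = False
    hypertension: bool = False
    chd: bool = False
    stroke: bool = False
    mi: bool = False
    baseline_egfr_band: str = ""
    bmi_cat: str = ""
    current_stage: Stage = Stage.NONE
    highest_stage: Stage = Stage.NONE
    person_slope: float = 0.0
    stages_attained: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.bmi_cat:
            self.bmi_cat = bmi_category(self.bmi)
        if not self.baseline_egfr_band:
            self.baseline_egfr_band = egfr_band(self.egfr)

    @property
    def any_cvd(self) -> bool:
        return self.chd or self.stroke or self.mi

    @property
    def obese(self) -> bool:
        return self.bmi_cat == "obesity"

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        errs: list[str] = []
        if self.alive and not self.egfr > 0:
            errs.append(f"person {self.id}: egfr must be > 0 while alive")
        if not (12.0 <= self.bmi <= 80.0):
            errs.append(f"person {self.id}: bmi {self.bmi} outside [12, 80]")
        if not (30.0 <= self.age <= 90.0):
            errs.append(f"person {self.id}: age {self.age} outside [30, 90]")
        if self.sex not in SEXES:
            errs.append(f"person {self.id}: unknown sex {self.sex!r}")
        if self.race not in RACES:
            errs.append(f"person {self.id}: unknown race {self.race!r}")
        if self.albuminuria not in ALBUMINURIA_LEVELS:
            errs.append(f"person {self.id}: unknown albuminuria {self.albuminuria!r}")
        if self.proteinuria_cat not in PROTEINURIA_CATEGORIES:
            errs.append(f"person {self.id}: unknown proteinuria {self.proteinuria_cat!r}")
        if self.bmi_cat != bmi_category(self.bmi):
            errs.append(
                f"person {self.id}: bmi_cat {self.bmi_cat!r} inconsistent with bmi {self.bmi}"
            )
        if self.baseline_egfr_band not in EGFR_BANDS:
            errs.append(f"person {self.id}: unknown eGFR band {self.baseline_egfr_band!r}")
        if self.highest_stage < self.current_stage:
            errs.append(f"person {self.id}: highest_stage below current_stage")
        return errs

    def raise_if_invalid(self) -> None:
        errs = self.validate()
        if errs:
            raise ValueError("; ".join(errs))


@dataclass
class LifetimeRecord:
    """Summary of one simulated life course."""

    id: int
    baseline_bmi_cat: str
    baseline_age_band: str
    baseline_egfr_band: str
    ever_ckd: bool
    highest_stage: Stage
    age_at_death_or_90: float
    died: bool
    attained: dict  # stage label -> bool, for s1..s5

    def validate(self) -> list[str]:
        errs: list[str] = []
        if self.ever_ckd != (self.highest_stage != Stage.NONE):
            errs.append(f"record {self.id}: ever_ckd inconsistent with highest_stage")
        attained_stages = [Stage.from_label(k) for k, v in self.attained.items() if v]
        top = max(attained_stages, default=Stage.NONE)
        if top != self.highest_stage:
            errs.append(f"record {self.id}: attainment flags do not reconstruct highest_stage")
        # GFR-defined stages at or below the highest GFR stage must be flagged
        for s in (Stage.S3A, Stage.S3B, Stage.S4, Stage.S5):
            if self.highest_stage >= s >= Stage.S3A and not self.attained.get(s.label, False):
                errs.append(f"record {self.id}: missing attainment flag for {s.label}")
        return errs
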