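"""Annual eGFR change and CKD stage assignment.

The annual change in eGFR for a person is modelled as

    Δ eGFR = base[band] + Σ covariate coefficients (current status) + ε

with band the baseline eGFR stratum (< 60 / ≥ 60, frozen at simulation
start) and ε a person-level random-slope deviation drawn from
Normal(0, sd[band]) — the ≥ 60 stratum's sd is shrunk by the square root of
the variance calibration multiplier.  Under the default
``once_at_baseline`` policy ε is drawn once per person and the covariate
part is recomputed every year as conditions switch on; ``annual_iid``
redraws ε every cycle.

Stages are the standard bands: ≥90 and 60–89 with kidney damage are stages
1–2, then 3a (45–59), 3b (30–44), 4 (15–29), 5 (<15) regardless of damage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import ProgressionParams, SimulationConfig
from .types import PersonState, Stage


@dataclass(frozen=True)
class StageThresholds:
    """eGFR stage boundaries (ml/min/1.73m², upper-exclusive below 60)."""

    s1_min: float = 90.0   # >= s1_min with damage -> s1
    s3a_max: float = 60.0  # < s3a_max             -> s3a
    s3b_max: float = 45.0  # < s3b_max             -> s3b
    s4_max: float = 30.0   # < s4_max              -> s4
    s5_max: float = 15.0   # < s5_max              -> s5

    def __post_init__(self):
        seq = (self.s1_min, self.s3a_max, self.s3b_max, self.s4_max, self.s5_max)
        if any(b <= a for a, b in zip(seq[1:], seq[:-1])):
            raise ValueError("stage thresholds must be strictly decreasing")


DEFAULT_THRESHOLDS = StageThresholds()

#: Minimum eGFR the engine will step down to (nonphysical values below this
#: are clipped; staging at the floor is stage 5).
EGFR_FLOOR = 1.0

_PROT_COEF = {"p1": None, "p2": "coef_prot_p2", "p3": "coef_prot_p3", "p4": "coef_prot_p4"}
_RACE_COEF = {"nh_white": None, "nh_black": "coef_nh_black",
              "hispanic": "coef_hispanic", "other": "coef_other"}


def mean_annual_change(person: PersonState, params: ProgressionParams) -> float:
    """Covariate mean of the annual eGFR change (ml/min/1.73m²/yr).

    Uses the person's *current* sex, race, proteinuria category, diabetes,
    hypertension, and obesity status, with the parameter column selected by
    the frozen baseline eGFR band.
    """
    band = person.baseline_egfr_band
    total = params.base_change[band]
    if person.sex == "female":
        total += params.coef_female[band]
    race_coef = _RACE_COEF[person.race]
    if race_coef:
        total += getattr(params, race_coef)[band]
    prot_coef = _PROT_COEF[person.proteinuria_cat]
    if prot_coef:
        total += getattr(params, prot_coef)[band]
    if person.diabetes:
        total += params.coef_diabetes[band]
    if person.hypertension:
        total += params.coef_hypertension[band]
    if person.obese:
        total += params.coef_obesity[band]
    return total


def draw_person_slope(person: PersonState, params: ProgressionParams,
                      rng: np.random.Generator,
                      config: SimulationConfig | None = None,
                      size: int | None = None):
    """Draw annual eGFR change(s) ~ Normal(mean_annual_change, sd[band]).

    In deterministic mode the SD collapses to zero and the covariate mean is
    returned exactly.  ``size`` draws a vector (for Monte-Carlo checks);
    the default returns a single float.
    """
    mean = mean_annual_change(person, params)
    sd = params.effective_sd(person.baseline_egfr_band)
    if config is not None and config.deterministic_mode:
        sd = 0.0
    if size is None:
        return float(rng.normal(mean, sd))
    return rng.normal(mean, sd, size=size)


def step_egfr(person: PersonState, slope_draw: float) -> PersonState:
    """Apply one annual eGFR increment, floored at :data:`EGFR_FLOOR`."""
    if not person.alive:
        raise ValueError("cannot step eGFR of a dead person")
    return replace(person, egfr=max(person.egfr + slope_draw, EGFR_FLOOR))


def assign_stage(egfr: float, albuminuria: str,
                 thresholds: StageThresholds = DEFAULT_THRESHOLDS) -> Stage:
    """CKD stage from eGFR and kidney damage (albuminuria ≥ moderate)."""
    if not egfr > 0:
        raise ValueError("eGFR must be > 0 for staging")
    if egfr < thresholds.s5_max:
        return Stage.S5
    if egfr < thresholds.s4_max:
        return Stage.S4
    if egfr < thresholds.s3b_max:
        return Stage.S3B
    if egfr < thresholds.s3a_max:
        return Stage.S3A
    if albuminuria in ("moderate", "severe"):
        return Stage.S1 if egfr >= thresholds.s1_min else Stage.S2
    return Stage.NONE


def gfr_stage_codes(egfr: np.ndarray,
                    thresholds: StageThresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Vectorized GFR-defined stage code (0 for eGFR ≥ 60, else 3..6)."""
    egfr = np.asarray(egfr, dtype=float)
    return np.select(
        [egfr < thresholds.s5_max, egfr < thresholds.s4_max,
         egfr < thresholds.s3b_max, egfr < thresholds.s3a_max],
        [int(Stage.S5), int(Stage.S4), int(Stage.S3B), int(Stage.S3A)],
        default=0,
    )


def assign_stage_codes(egfr: np.ndarray, damage: np.ndarray,
                       thresholds: StageThresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Vectorized :func:`assign_stage` over integer stage codes."""
    g = gfr_stage_codes(egfr, thresholds)
    damage_stage = np.where(np.asarray(egfr) >= thresholds.s1_min,
                            int(Stage.S1), int(Stage.S2))
    return np.where(g > 0, g, np.where(np.asarray(damage, bool), damage_stage, 0))


def update_stage_history(person: PersonState, new_stage: Stage,
                         pass_through_staging: bool = True) -> PersonState:
    """Ratchet the highest attained stage and record attainment.

    With pass-through staging on, an annual step that skips GFR bands (for
    example 3a directly to 4) marks every intermediate GFR-defined stage as
    attained, so the sequential-stage bookkeeping holds across large drops.
    """
    attained = set(person.stages_attained)
    if new_stage != Stage.NONE:
        attained.add(new_stage)
    if pass_through_staging and new_stage >= Stage.S3A:
        for s in (Stage.S3A, Stage.S3B, Stage.S4, Stage.S5):
            if s <= new_stage:
                attained.add(s)
    highest = max(person.highest_stage, new_stage)
    return replace(person, current_stage=new_stage, highest_stage=highest,
                   stages_attained=attained)
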