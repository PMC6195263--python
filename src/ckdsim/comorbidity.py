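"""Annual comorbidity updates: BMI drift, incident conditions, and death.

Relative risks act multiplicatively on the annual background probability,
capped at 1 — exact for small probabilities and monotone, documented as an
approximation to hazard-scale scaling.  All conditions are absorbing, and
albuminuria severity never decreases.  There is no direct BMI term in
mortality: obesity influences death only through acquired CVD and CKD stage.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .cohort import map_albuminuria_to_proteinuria
from .params import BackgroundRates, ObesityParams
from .types import PersonState, bmi_category

#: Draw order of the scalar incident-event update (one uniform each).
INCIDENT_EVENTS = ("diabetes", "hypertension", "chd", "stroke", "mi")


def apply_relative_risk(base_prob: float, rr: float) -> float:
    """min(1, base_prob × rr): risk-scale multiplication with cap."""
    if not 0.0 <= base_prob <= 1.0:
        raise ValueError("base probability must be in [0, 1]")
    if rr < 0:
        raise ValueError("relative risk must be >= 0")
    return min(1.0, base_prob * rr)


def update_bmi(person: PersonState, obesity_params: ObesityParams) -> PersonState:
    """Apply one year of BMI drift and recompute the BMI category."""
    if not person.alive:
        raise ValueError("cannot update BMI of a dead person")
    bmi = person.bmi + obesity_params.annual_bmi_change(person.age, person.race, person.sex)
    return replace(person, bmi=bmi, bmi_cat=bmi_category(bmi))


def incident_events(person: PersonState, background: BackgroundRates,
                    obesity_params: ObesityParams,
                    rng: np.random.Generator) -> PersonState:
    """One annual cycle of incident conditions for a single person.

    Each absent condition independently becomes present with probability
    background rate × applicable BMI relative risk.  Albuminuria advances at
    most one level per year (normal→moderate, moderate→severe), with the
    normal→moderate rate multiplied by the diabetes/hypertension factors.
    The proteinuria covariate tracks albuminuria and never moves down.
    """
    if not person.alive:
        raise ValueError("cannot apply incident events to a dead person")
    female = person.sex == "female"
    updates: dict = {}
    for event in INCIDENT_EVENTS:
        u = rng.random()
        if getattr(person, event):
            continue  # absorbing
        base = float(background.annual_prob(event, person.age, female))
        p = apply_relative_risk(base, obesity_params.rr(event, person.bmi_cat, person.sex))
        if u < p:
            updates[event] = True

    u_alb = rng.random()
    u_sev = rng.random()
    if person.albuminuria == "normal":
        base = float(background.annual_prob("albuminuria", person.age, female))
        mult = 1.0
        if person.diabetes or updates.get("diabetes"):
            mult *= background.albuminuria_rr_diabetes
        if person.hypertension or updates.get("hypertension"):
            mult *= background.albuminuria_rr_hypertension
        if u_alb < apply_relative_risk(base, mult):
            updates["albuminuria"] = "moderate"
    elif person.albuminuria == "moderate":
        base = float(background.annual_prob("albuminuria_severe", person.age, female))
        if u_sev < min(1.0, base):
            updates["albuminuria"] = "severe"

    out = replace(person, **updates)
    if "albuminuria" in updates:
        new_prot = map_albuminuria_to_proteinuria(out.albuminuria)
        if new_prot > out.proteinuria_cat:  # p1 < p2 < p3 < p4 lexicographically
            out = replace(out, proteinuria_cat=new_prot)
    return out


def mortality_prob(person: PersonState, background: BackgroundRates) -> float:
    """Annual death probability: life-table rate × stage HR × CVD HR.

    Deliberately contains no BMI multiplier: with full adjustment the
    evidence base shows no direct obesity effect on non-CVD mortality, so
    obesity acts on survival only through CVD and CKD stage.
    """
    q = float(background.mortality_prob(person.age, person.sex == "female"))
    q *= background.hr_mortality_by_stage[person.current_stage.label]
    if person.any_cvd:
        q *= background.hr_mortality_cvd
    return min(1.0, q)


def mortality_draw(person: PersonState, background: BackgroundRates,
                   rng: np.random.Generator) -> PersonState:
    """Draw this cycle's survival; dead persons keep all other state."""
    if not person.alive:
        raise ValueError("person is already dead")
    if rng.random() < mortality_prob(person, background):
        return replace(person, alive=False)
    return person
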