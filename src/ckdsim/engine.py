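"""Annual-cycle life-course simulator.

Each simulated year applies, in this fixed order: (1) mortality draw;
(2) BMI drift; (3) incident conditions (diabetes, hypertension, CHD,
stroke, MI, albuminuria); (4) the eGFR step from the person's slope;
(5) stage assignment and history; then the person ages one year.  The loop
ends at death or when age reaches the horizon (90 by default).  The update
order is a single global constant — it is not configurable because
reordering changes results slightly and there is no empirical anchor for
any other order.

Randomness is organised as one counter-based (Philox) stream per person,
keyed by (master seed, person id).  Every person consumes a fixed layout of
draws — eight uniform channels per cycle plus one standard normal per cycle
and one at baseline — so results are independent of cohort order and of
what happens to other persons.

The whole cohort is advanced with numpy array operations; the scalar
single-person operations in :mod:`ckdsim.progression` and
:mod:`ckdsim.comorbidity` define the same transition rules and serve as the
cross-checked reference path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import ParamBundle
from .progression import EGFR_FLOOR, assign_stage_codes, gfr_stage_codes
from .types import (
    BMI_CATEGORIES,
    BMI_CUTOFFS,
    PROTEINURIA_CATEGORIES,
    RACES,
    SEXES,
    LifetimeRecord,
    Stage,
    baseline_age_band,
)

# uniform channels, one per (person, cycle)
_CH_MORT, _CH_DIA, _CH_HTN, _CH_CHD, _CH_STROKE, _CH_MI, _CH_ALB, _CH_ALBSEV = range(8)
_N_CHANNELS = 8

#: Columns of the lifetime-record table produced by :func:`simulate_cohort`.
RECORD_COLUMNS = (
    "id", "baseline_bmi_cat", "baseline_age_band", "baseline_egfr_band",
    "ever_ckd", "highest_stage", "age_at_death_or_90", "died",
    "attained_s1", "attained_s2", "attained_s3a", "attained_s3b",
    "attained_s4", "attained_s5",
)

_ATTAINED_COLS = RECORD_COLUMNS[8:]


def person_streams(ids: np.ndarray, n_cycles: np.ndarray, master_seed: int):
    """Pre-draw each person's random numbers from their own Philox stream.

    Returns ``U`` of shape (n, maxT, 8) with uniforms and ``Z`` of shape
    (n, maxT+1) with standard normals (index 0 is the baseline slope draw).
    The stream for person *i* depends only on (master_seed, ids[i]) and the
    number of cycles they can live, never on cohort order.
    """
    n = len(ids)
    max_t = int(n_cycles.max()) if n else 0
    U = np.zeros((n, max_t, _N_CHANNELS))
    Z = np.zeros((n, max_t + 1))
    base = int(master_seed) << 64
    for i in range(n):
        g = np.random.Generator(np.random.Philox(key=base + int(ids[i])))
        t = int(n_cycles[i])
        if t > 0:
            U[i, :t, :] = g.random((t, _N_CHANNELS))
        Z[i, : t + 1] = g.standard_normal(t + 1)
    return U, Z


def _codes(values, domain) -> np.ndarray:
    lut = {v: i for i, v in enumerate(domain)}
    return np.fromiter((lut[v] for v in values), dtype=np.int64, count=len(values))


def simulate_cohort(cohort: pd.DataFrame, bundle: ParamBundle,
                    master_seed: int | None = None,
                    collect_trajectories: bool = False):
    """Simulate every person in *cohort* to death or the age horizon.

    Parameters
    ----------
    cohort
        Baseline table in the cohort CSV schema (persistent albuminuria
        already resolved).  An optional ``proteinuria`` column overrides the
        default albuminuria→proteinuria mapping.
    bundle
        Full parameter bundle; ``bundle.simulation`` supplies the horizon,
        determinism switches and the default master seed.
    master_seed
        Seed for the per-person random streams; defaults to
        ``bundle.simulation.master_seed``.
    collect_trajectories
        Also return a per-person-per-year log (id, year, age, egfr, stage,
        albuminuria, diabetes, hypertension, bmi).

    Returns the lifetime-record DataFrame (one row per person, columns
    :data:`RECORD_COLUMNS`), plus the trajectory DataFrame when requested.
    """
    prog, obes, back, sim = bundle
    if master_seed is None:
        master_seed = sim.master_seed
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort is empty")
    ids = cohort["id"].to_numpy(np.int64)
    if len(np.unique(ids)) != n:
        raise ValueError("cohort ids must be unique")

    age = cohort["age"].to_numpy(float).copy()
    if np.any((age < 30) | (age > sim.max_age)):
        raise ValueError(f"baseline ages must lie in [30, {sim.max_age}]")
    female = cohort["sex"].to_numpy() == "female"
    race = _codes(cohort["race"].to_numpy(), RACES)
    egfr = cohort["egfr"].to_numpy(float).copy()
    if np.any(egfr <= 0):
        raise ValueError("baseline eGFR must be > 0")
    alb = _codes(cohort["albuminuria"].to_numpy(), ("normal", "moderate", "severe"))
    dia = cohort["diabetes"].to_numpy().astype(bool).copy()
    htn = cohort["hypertension"].to_numpy().astype(bool).copy()
    chd = cohort["chd"].to_numpy().astype(bool).copy()
    stroke = cohort["stroke"].to_numpy().astype(bool).copy()
    mi = cohort["mi"].to_numpy().astype(bool).copy()
    bmi = cohort["bmi"].to_numpy(float).copy()

    band = (egfr >= 60).astype(np.int64)  # 0 = lt60, 1 = ge60 (frozen)
    band_lab = np.where(band == 1, "ge60", "lt60")
    bmi_cat = np.digitize(bmi, BMI_CUTOFFS)
    base_bmi_cat = np.array(BMI_CATEGORIES, dtype=object)[bmi_cat]
    base_age_band = np.array([baseline_age_band(a) for a in age], dtype=object)

    if "proteinuria" in cohort.columns:
        prot = _codes(cohort["proteinuria"].to_numpy(), PROTEINURIA_CATEGORIES)
    else:
        prot = alb.copy()  # normal->p1(0), moderate->p2(1), severe->p3(2)

    # ---- coefficient lookup tables (band-indexed) -------------------------
    def bandvec(m: dict) -> np.ndarray:
        return np.array([m["lt60"], m["ge60"]], dtype=float)

    base_change = bandvec(prog.base_change)
    c_female = bandvec(prog.coef_female)
    c_race = np.zeros((4, 2))
    c_race[1] = bandvec(prog.coef_nh_black)
    c_race[2] = bandvec(prog.coef_hispanic)
    c_race[3] = bandvec(prog.coef_other)
    c_prot = np.zeros((4, 2))
    c_prot[1] = bandvec(prog.coef_prot_p2)
    c_prot[2] = bandvec(prog.coef_prot_p3)
    c_prot[3] = bandvec(prog.coef_prot_p4)
    c_dia = bandvec(prog.coef_diabetes)
    c_htn = bandvec(prog.coef_hypertension)
    c_obese = bandvec(prog.coef_obesity)
    sd_eff = np.array([prog.effective_sd("lt60"), prog.effective_sd("ge60")])
    if sim.deterministic_mode:
        sd_eff = np.zeros(2)

    rr_dia = np.ones((4, 2))
    rr_htn = np.ones((4, 2))
    for ci, cat in ((2, "overweight"), (3, "obesity")):
        for si, sex in enumerate(SEXES):
            rr_dia[ci, si] = obes.rr_diabetes[cat][sex]
            rr_htn[ci, si] = obes.rr_hypertension[cat][sex]
    rr_chd = np.ones(4)
    rr_stroke = np.ones(4)
    rr_mi = np.ones(4)
    for ci, cat in ((2, "overweight"), (3, "obesity")):
        rr_chd[ci] = obes.rr_chd[cat]
        rr_stroke[ci] = obes.rr_stroke[cat]
        rr_mi[ci] = obes.rr_mi[cat]

    # bmi_delta[age50plus, race_group, sex]
    bmi_delta = np.zeros((2, 2, 2))
    for ai, aband in enumerate(("30-49", "50+")):
        for gi, group in enumerate(("white", "black")):
            for si, sex in enumerate(SEXES):
                bmi_delta[ai, gi, si] = obes.bmi_delta[aband][group][sex]
    race_group = np.array(
        [0 if obes.race_to_bmi_group[r] == "white" else 1 for r in RACES]
    )[race]
    sex_idx = female.astype(np.int64)

    stage_hr = np.array([back.hr_mortality_by_stage[s.label] for s in Stage])

    # ---- random streams ---------------------------------------------------
    cycles = np.maximum(sim.max_age - age.astype(int), 0)
    U, Z = person_streams(ids, cycles, master_seed)
    eps = Z[:, 0] * sd_eff[band]  # person-level random slope deviation

    # ---- state ------------------------------------------------------------
    alive = np.ones(n, dtype=bool)
    death_age = np.full(n, float(sim.max_age))
    attained = np.zeros((n, 7), dtype=bool)

    def mean_change() -> np.ndarray:
        return (
            base_change[band]
            + np.where(female, c_female[band], 0.0)
            + c_race[race, band]
            + c_prot[prot, band]
            + np.where(dia, c_dia[band], 0.0)
            + np.where(htn, c_htn[band], 0.0)
            + np.where(bmi_cat == 3, c_obese[band], 0.0)
        )

    damage = alb >= 1
    cur = assign_stage_codes(egfr, damage)
    highest = cur.copy()
    max_gfr = gfr_stage_codes(egfr)
    attained[np.arange(n), cur] = cur > 0
    if sim.pass_through_staging:
        for lvl in (3, 4, 5, 6):
            attained[:, lvl] |= max_gfr >= lvl

    traj: list[pd.DataFrame] | None = [] if collect_trajectories else None
    stage_labels = np.array([s.label for s in Stage], dtype=object)
    if collect_trajectories:
        traj.append(_traj_frame(ids, sim.start_year, age, egfr, cur, stage_labels,
                                alb, dia, htn, bmi, np.ones(n, dtype=bool)))

    max_t = int(cycles.max())
    for t in range(max_t):
        active = alive & (t < cycles)
        if not active.any():
            break
        u = U[:, t, :]

        # 1. mortality
        q = back.mortality_prob(age, female) * stage_hr[cur]
        q = np.minimum(q * np.where(chd | stroke | mi, back.hr_mortality_cvd, 1.0), 1.0)
        dies = active & (u[:, _CH_MORT] < q)
        alive[dies] = False
        death_age[dies] = age[dies]
        act = active & alive

        # 2. BMI drift
        delta = bmi_delta[(age >= 50).astype(int), race_group, sex_idx]
        bmi = np.where(act, bmi + delta, bmi)
        bmi_cat = np.digitize(bmi, BMI_CUTOFFS)

        # 3. incident conditions (absorbing)
        new_dia = act & ~dia & (
            u[:, _CH_DIA] < np.minimum(
                back.annual_prob("diabetes", age, female) * rr_dia[bmi_cat, sex_idx], 1.0)
        )
        dia |= new_dia
        new_htn = act & ~htn & (
            u[:, _CH_HTN] < np.minimum(
                back.annual_prob("hypertension", age, female) * rr_htn[bmi_cat, sex_idx], 1.0)
        )
        htn |= new_htn
        chd |= act & ~chd & (
            u[:, _CH_CHD] < np.minimum(
                back.annual_prob("chd", age, female) * rr_chd[bmi_cat], 1.0)
        )
        stroke |= act & ~stroke & (
            u[:, _CH_STROKE] < np.minimum(
                back.annual_prob("stroke", age, female) * rr_stroke[bmi_cat], 1.0)
        )
        mi |= act & ~mi & (
            u[:, _CH_MI] < np.minimum(
                back.annual_prob("mi", age, female) * rr_mi[bmi_cat], 1.0)
        )

        # albuminuria: at most one level per year; the normal->moderate rate
        # reflects this cycle's (possibly newly acquired) diabetes/hypertension
        alb_mult = np.where(dia, back.albuminuria_rr_diabetes, 1.0) * np.where(
            htn, back.albuminuria_rr_hypertension, 1.0)
        p_mod = np.minimum(back.annual_prob("albuminuria", age, female) * alb_mult, 1.0)
        to_moderate = act & (alb == 0) & (u[:, _CH_ALB] < p_mod)
        p_sev = np.minimum(back.annual_prob("albuminuria_severe", age, female), 1.0)
        to_severe = act & (alb == 1) & (u[:, _CH_ALBSEV] < p_sev)
        alb = alb + to_moderate + to_severe
        prot = np.maximum(prot, alb)  # proteinuria covariate tracks albuminuria

        # 4. eGFR step (covariate mean is time-updated; eps is the person draw)
        if sim.slope_redraw_policy == "annual_iid":
            eps = Z[:, t + 1] * sd_eff[band]
        slope = mean_change() + eps
        egfr = np.where(act, np.maximum(egfr + slope, EGFR_FLOOR), egfr)

        # 5. staging
        new_stage = assign_stage_codes(egfr, alb >= 1)
        max_gfr = np.where(act, np.maximum(max_gfr, gfr_stage_codes(egfr)), max_gfr)
        for code in (1, 2):
            attained[:, code] |= act & (new_stage == code)
        if sim.pass_through_staging:
            for lvl in (3, 4, 5, 6):
                attained[:, lvl] |= act & (max_gfr >= lvl)
        else:
            for lvl in (3, 4, 5, 6):
                attained[:, lvl] |= act & (new_stage == lvl)
        highest = np.where(act, np.maximum(highest, new_stage), highest)
        # stage 5 is absorbing for staging purposes (mortality keeps the
        # stage-5 hazard even if eGFR drifts back over the boundary)
        cur = np.where(act, np.where(attained[:, 6], 6, new_stage), cur)

        age = np.where(act, age + 1, age)
        if collect_trajectories:
            traj.append(_traj_frame(ids, sim.start_year + t + 1, age, egfr, cur,
                                    stage_labels, alb, dia, htn, bmi, act))

    records = pd.DataFrame(
        {
            "id": ids,
            "baseline_bmi_cat": base_bmi_cat,
            "baseline_age_band": base_age_band,
            "baseline_egfr_band": band_lab,
            "ever_ckd": highest > 0,
            "highest_stage": stage_labels[highest],
            "age_at_death_or_90": death_age,
            "died": ~alive,
            **{col: attained[:, i + 1] for i, col in enumerate(_ATTAINED_COLS)},
        }
    )
    if collect_trajectories:
        return records, pd.concat(traj, ignore_index=True)
    return records


def _traj_frame(ids, year, age, egfr, cur, stage_labels, alb, dia, htn, bmi, mask):
    alb_labels = np.array(("normal", "moderate", "severe"), dtype=object)
    return pd.DataFrame(
        {
            "id": ids[mask],
            "year": year,
            "age": age[mask],
            "egfr": egfr[mask],
            "stage": stage_labels[cur[mask]],
            "albuminuria": alb_labels[alb[mask]],
            "diabetes": dia[mask].astype(int),
            "hypertension": htn[mask].astype(int),
            "bmi": bmi[mask],
        }
    )


def simulate_person(person, bundle: ParamBundle,
                    master_seed: int | None = None) -> LifetimeRecord:
    """Simulate a single :class:`~ckdsim.types.PersonState` to completion.

    Thin wrapper over :func:`simulate_cohort` with a one-person cohort; the
    person's random stream is identical to what they would receive inside
    any cohort simulated under the same master seed.
    """
    row = pd.DataFrame(
        {
            "id": [person.id], "age": [person.age], "sex": [person.sex],
            "race": [person.race], "egfr": [person.egfr],
            "albuminuria": [person.albuminuria],
            "proteinuria": [person.proteinuria_cat],
            "diabetes": [int(person.diabetes)], "hypertension": [int(person.hypertension)],
            "chd": [int(person.chd)], "stroke": [int(person.stroke)],
            "mi": [int(person.mi)], "bmi": [person.bmi],
        }
    )
    rec = simulate_cohort(row, bundle, master_seed=master_seed).iloc[0]
    return record_from_row(rec)


def record_from_row(row) -> LifetimeRecord:
    """Convert one row of the record table to a :class:`LifetimeRecord`."""
    return LifetimeRecord(
        id=int(row["id"]),
        baseline_bmi_cat=row["baseline_bmi_cat"],
        baseline_age_band=row["baseline_age_band"],
        baseline_egfr_band=row["baseline_egfr_band"],
        ever_ckd=bool(row["ever_ckd"]),
        highest_stage=Stage.from_label(row["highest_stage"]),
        age_at_death_or_90=float(row["age_at_death_or_90"]),
        died=bool(row["died"]),
        attained={
            lab: bool(row[f"attained_{lab}"])
            for lab in ("s1", "s2", "s3a", "s3b", "s4", "s5")
        },
    )
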