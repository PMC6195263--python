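"""Lifetime-risk tabulation, percentile-bootstrap CIs, group comparison,
and the one-way ±25% sensitivity analyses.

The lifetime risk of any CKD in a group is the fraction of simulated life
courses that ever reach stage 1–5; the highest-stage shares partition that
fraction exactly (each person contributes to the one stage that is their
lifetime maximum).  Confidence intervals come from a percentile bootstrap:
persons are resampled with replacement and re-simulated, and the interval
is read off the replicate distribution with linearly interpolated
percentiles.  By default every replicate also receives fresh simulation
randomness, so both cohort-sampling and Monte-Carlo uncertainty propagate;
``fresh_sim=False`` restricts the bootstrap to cohort resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import simulate_cohort
from .params import ParamBundle, scale_param
from .types import CKD_STAGE_LABELS

_RISK_METRICS = ("risk_any",) + tuple(f"share_{s}" for s in CKD_STAGE_LABELS)


def lifetime_risk(records: pd.DataFrame, by=("baseline_bmi_cat",)) -> pd.DataFrame:
    """Tabulate lifetime risk by group.

    Returns one row per group with columns ``n``, ``risk_any`` and
    ``share_s1`` … ``share_s5`` (proportion whose *highest* attained stage
    is that stage).  Groups requested but not present in the records are
    reported with ``n = 0`` and missing (NaN) proportions, never zero.
    """
    if len(records) == 0:
        raise ValueError("no records to tabulate")
    by = list(by)
    rows = []
    for key, grp in records.groupby(by, sort=True, observed=False):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        row = dict(zip(by, key))
        row["n"] = n
        if n == 0:
            row["risk_any"] = np.nan
            for s in CKD_STAGE_LABELS:
                row[f"share_{s}"] = np.nan
        else:
            row["risk_any"] = grp["ever_ckd"].mean()
            counts = grp["highest_stage"].value_counts()
            for s in CKD_STAGE_LABELS:
                row[f"share_{s}"] = counts.get(s, 0) / n
        rows.append(row)
    return pd.DataFrame(rows)


def _derive_seed(master_seed: int, k: int) -> int:
    """Independent 31-bit child seed for replicate *k*."""
    return int(np.random.SeedSequence([int(master_seed), int(k)]).generate_state(1)[0]
               & 0x7FFFFFFF)


def bootstrap_ci(cohort: pd.DataFrame, bundle: ParamBundle,
                 B: int | None = None, percentiles=None,
                 master_seed: int | None = None, by=("baseline_bmi_cat",),
                 fresh_sim: bool = True):
    """Percentile-bootstrap CIs for every cell of the lifetime-risk table.

    Each of the ``B`` replicates resamples the cohort with replacement and
    re-simulates it; the CI for each (group, metric) cell is the
    (2.5th, 97.5th) percentile — linear interpolation between order
    statistics — of the replicate estimates.

    Returns ``(table, replicates)``: the point-estimate table augmented
    with ``<metric>_ci_low`` / ``<metric>_ci_high`` columns, and the long
    replicate table (columns ``rep`` + group + metrics) for paired tests.
    """
    sim = bundle.simulation
    if B is None:
        B = sim.bootstrap_reps
    if B < 1:
        raise ValueError("bootstrap replicate count must be >= 1")
    if percentiles is None:
        percentiles = sim.ci_percentiles
    if master_seed is None:
        master_seed = sim.master_seed
    by = list(by)

    point = lifetime_risk(simulate_cohort(cohort, bundle, master_seed=master_seed), by)

    n = len(cohort)
    rep_rows = []
    for r in range(B):
        resample_rng = np.random.default_rng(_derive_seed(master_seed, 2 * r + 1))
        idx = resample_rng.integers(0, n, size=n)
        boot = cohort.iloc[idx].reset_index(drop=True)
        boot["id"] = np.arange(n, dtype=np.int64)  # positional streams
        sim_seed = _derive_seed(master_seed, 2 * r + 2) if fresh_sim \
            else _derive_seed(master_seed, 0)
        table = lifetime_risk(simulate_cohort(boot, bundle, master_seed=sim_seed), by)
        table.insert(0, "rep", r)
        rep_rows.append(table)
    reps = pd.concat(rep_rows, ignore_index=True)

    lo_p, hi_p = percentiles
    out = point.copy()
    for metric in _RISK_METRICS:
        lo, hi = [], []
        for _, row in point.iterrows():
            mask = np.ones(len(reps), dtype=bool)
            for col in by:
                mask &= reps[col].to_numpy() == row[col]
            vals = reps.loc[mask, metric].dropna().to_numpy()
            if len(vals) == 0:
                lo.append(np.nan)
                hi.append(np.nan)
            else:
                lo.append(np.percentile(vals, lo_p))
                hi.append(np.percentile(vals, hi_p))
        out[f"{metric}_ci_low"] = lo
        out[f"{metric}_ci_high"] = hi
    return out, reps


def percentile_interval(values, percentiles=(2.5, 97.5)) -> tuple:
    """The declared percentile rule (linear interpolation), exposed for
    direct use on an injected replicate vector."""
    values = np.asarray(values, dtype=float)
    lo, hi = percentiles
    return float(np.percentile(values, lo)), float(np.percentile(values, hi))


@dataclass
class ComparisonResult:
    """Paired-replicate comparison of a metric between two groups."""

    mean_diff: float
    se_boot: float
    p_value: float
    zero_variance: bool = False


def compare_groups(reps_a, reps_b) -> ComparisonResult:
    """Two-sided p-value for a difference via paired bootstrap replicates.

    With replicate estimates paired by seed, p = 2Φ(−|d̄|/SE) where d̄ is
    the mean paired difference and SE the standard deviation of the
    replicate differences (the bootstrap standard error).  This normal
    approximation is a declared convention.  Zero bootstrap variance with a
    nonzero difference is reported as p < 1/B with a flag.
    """
    a = np.asarray(reps_a, dtype=float)
    b = np.asarray(reps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate vectors must be paired (equal length)")
    d = a - b
    mean = float(d.mean())
    se = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    if se <= 1e-12 * max(1.0, abs(mean)):  # numerically zero variance
        se = 0.0
    if se == 0.0:
        if mean == 0.0:
            return ComparisonResult(mean, 0.0, 1.0)
        return ComparisonResult(mean, 0.0, 1.0 / len(d), zero_variance=True)
    p = float(2.0 * stats.norm.sf(abs(mean) / se))
    return ComparisonResult(mean, se, p)


#: The three parameters varied ±25% in the one-way sensitivity analyses.
SENSITIVITY_PARAMS = ("rr_diabetes_obesity", "rr_hypertension_obesity", "coef_obesity")
SENSITIVITY_FACTORS = (0.75, 1.25)


def run_sensitivity(cohort: pd.DataFrame, bundle: ParamBundle,
                    master_seed: int | None = None) -> pd.DataFrame:
    """Six one-way ±25% sensitivity analyses on the obesity parameters.

    For each of the three obesity-related parameters and each factor, the
    bundle is rebuilt with only that parameter scaled and the cohort is
    re-simulated under identical seeds; the reported outcome is the
    difference in lifetime risk of any CKD between the obesity and
    normal-weight baseline groups (percentage-point scale as a proportion).
    The unscaled reference difference is included as the first row.
    """
    if master_seed is None:
        master_seed = bundle.simulation.master_seed

    def obesity_minus_normal(b: ParamBundle) -> float:
        table = lifetime_risk(simulate_cohort(cohort, b, master_seed=master_seed))
        risk = table.set_index("baseline_bmi_cat")["risk_any"]
        for cat in ("obesity", "normal"):
            if cat not in risk.index or not np.isfinite(risk[cat]):
                raise ValueError(
                    f"sensitivity cohort must contain a baseline {cat!r} group"
                )
        return float(risk["obesity"] - risk["normal"])

    ref = obesity_minus_normal(bundle)
    rows = [{"parameter": "reference", "factor": 1.0, "diff_any_ckd": ref,
             "reference_diff": ref}]
    for param in SENSITIVITY_PARAMS:
        for factor in SENSITIVITY_FACTORS:
            scaled = scale_param(bundle, param, factor)
            rows.append(
                {
                    "parameter": param,
                    "factor": factor,
                    "diff_any_ckd": obesity_minus_normal(scaled),
                    "reference_diff": ref,
                }
            )
    return pd.DataFrame(rows)
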