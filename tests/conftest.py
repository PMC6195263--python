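import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ckdsim as ck

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    return ck.load_params()


@pytest.fixture(scope="session")
def quiet_bundle(bundle):
    """Bundle with zero background incidence and zero mortality: covariates
    are frozen at baseline, nobody dies, slopes stay constant."""
    back = ck.BackgroundRates.flat(incidence=0.0, mortality=0.0)
    return ck.ParamBundle(bundle.progression, bundle.obesity, back, bundle.simulation)


@pytest.fixture(scope="session")
def small_cohort():
    spec = ck.default_cohort_spec(n=400, seed=91)
    coh = ck.generate_cohort(spec)
    return ck.adjust_persistent_albuminuria(coh, spec.albuminuria_retain_prob, seed=92)


def make_person(**overrides):
    defaults = dict(id=0, age=50, sex="male", race="nh_white", egfr=95.0, bmi=24.0)
    defaults.update(overrides)
    return ck.PersonState(**defaults)


def cohort_row(pid, age, egfr, albuminuria="normal", sex="male", race="nh_white",
               bmi=24.0, diabetes=0, hypertension=0, chd=0, stroke=0, mi=0,
               proteinuria=None):
    row = {
        "id": pid, "age": age, "sex": sex, "race": race,
        "scr_mg_dl": ck.scr_from_egfr(egfr, age, sex, race), "egfr": egfr,
        "albuminuria": albuminuria, "diabetes": diabetes,
        "hypertension": hypertension, "chd": chd, "stroke": stroke, "mi": mi,
        "bmi": bmi,
    }
    if proteinuria is not None:
        row["proteinuria"] = proteinuria
    return row


def cohort_frame(rows):
    return pd.DataFrame(rows)
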