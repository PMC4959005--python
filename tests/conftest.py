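import numpy as np
import pandas as pd
import pytest

import dislife as dl


@pytest.fixture(scope="session")
def operating_point_curves():
    """Constant annual hazards at a realistic diabetic operating point:
    onset 6.7/100 PY, recovery 15.9, death 2.9 (non-disabled) / 4.5 (disabled)."""
    c = dl.constant_curves(0.067, 0.159, 0.029, 0.045)
    return {(s, g): c for s in ("male", "female") for g in ("diabetes", "no_diabetes")}


@pytest.fixture(scope="session")
def constant_config(operating_point_curves):
    return dl.SyntheticConfig(
        n_persons=20_000,
        seed=20,
        curves=operating_point_curves,
        missingness=None,
        baseline_disability_prevalence=0.10,
    )


@pytest.fixture(scope="session")
def constant_panel(constant_config):
    return dl.simulate_panel(constant_config)


@pytest.fixture(scope="session")
def small_panel():
    """Default-curve panel with attrition on, small enough for fast tests."""
    cfg = dl.SyntheticConfig(n_persons=1500, seed=11)
    return dl.simulate_panel(cfg)


@pytest.fixture()
def tiny_panel():
    """Hand-built four-person, three-wave panel covering the main cases:
    person 0 stays non-disabled; person 1 becomes disabled at wave 1;
    person 2 dies between waves 1 and 2; person 3 is prevalent-disabled
    at baseline."""
    rows = []
    mob_free = [False] * 5
    mob_dis = [True, True, True, True, False]
    other_free = [False] * 5
    other_dis = [True, False, False, False, False]

    def rec(pid, wave, alive, responded, disabled, death_year=pd.NA, diabetes=False):
        base = {
            "person_id": pid,
            "wave": wave,
            "interview_year": 1992 + 2 * wave,
            "birth_year": 1936,
            "age": 56 + 2 * wave,
            "sex": "male" if pid % 2 == 0 else "female",
            "sample_weight": 1.0,
            "alive": alive,
            "death_year": death_year,
            "responded": responded,
            "diabetes": diabetes if responded else pd.NA,
        }
        mob = mob_dis if disabled else mob_free
        oth = other_dis if disabled else other_free
        for i in range(5):
            base[f"mob{i+1}"] = mob[i] if responded else pd.NA
            base[f"iadl{i+1}"] = oth[i] if responded else pd.NA
            base[f"adl{i+1}"] = oth[i] if responded else pd.NA
        return base

    rows += [rec(0, w, True, True, False) for w in range(3)]
    rows += [rec(1, 0, True, True, False), rec(1, 1, True, True, True),
             rec(1, 2, True, True, True, diabetes=True)]
    rows += [rec(2, 0, True, True, False), rec(2, 1, True, True, False),
             rec(2, 2, False, False, False, death_year=1995)]
    rows += [rec(3, 0, True, True, True), rec(3, 1, True, True, True),
             rec(3, 2, True, True, False)]
    df = pd.DataFrame(rows)
    for c in [f"mob{i}" for i in range(1, 6)] + [f"iadl{i}" for i in range(1, 6)] + [
        f"adl{i}" for i in range(1, 6)
    ] + ["diabetes"]:
        df[c] = df[c].astype("boolean")
    return df
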