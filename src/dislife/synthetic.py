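"""Synthetic biennial disability panels with known transition dynamics.

Emulates the structure of a Health and Retirement Study style survey: two
birth-cohort windows (1931-41 baseline 1992; 1942-47 baseline 2002),
interviews every two years, item-level disability reports in three domains
(5 mobility, 5 IADL, 5 ADL items), self-reported diabetes diagnosis,
death years observed exactly (as under death-index linkage), wave-level
nonresponse, and positive heterogeneous sampling weights.

Each person evolves *annually* through the five-state disability model in
:mod:`dislife.markov` using logit-linear-in-age hazard curves for their
(sex, diabetes group); only even-offset years are emitted as waves.  Item
responses are drawn so the domain classification rule recovers the latent
disabled / non-disabled state exactly, which makes the classify-then-
estimate pipeline an identity in expectation while still exercising
item-level coding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .markov import (
    DEAD,
    LTD,
    ND,
    NDH,
    STD,
    LifeTableSummary,
    MarkovSpec,
    run_cohort,
    summarize,
)

SEXES = ("male", "female")
GROUPS = ("diabetes", "no_diabetes")
DOMAINS = ("mobility", "iadl", "adl")

ITEM_COLUMNS = tuple(
    f"{dom}{i}" for dom in ("mob", "iadl", "adl") for i in range(1, 6)
)

PANEL_COLUMNS = (
    "person_id",
    "wave",
    "interview_year",
    "birth_year",
    "age",
    "sex",
    "sample_weight",
    "alive",
    "death_year",
    "responded",
    "diabetes",
) + ITEM_COLUMNS


class ConfigurationError(ValueError):
    """Invalid synthetic-panel configuration."""


@dataclass(frozen=True)
class TransitionCurves:
    """Logit-linear annual hazard curves: logit p(age) = b0 + b1 * (age - 50).

    Four transitions: disability onset, recovery (remission), death while
    non-disabled, death while disabled.  Each is an (intercept, slope)
    pair; the slope is per year of age.
    """

    onset: tuple[float, float]
    recovery: tuple[float, float]
    death_nd: tuple[float, float]
    death_dis: tuple[float, float]

    def probability(self, transition: str, age: float) -> float:
        b0, b1 = getattr(self, transition)
        return float(expit(b0 + b1 * (age - 50.0)))

    def at_age(self, age: float) -> tuple[float, float, float, float]:
        return (
            self.probability("onset", age),
            self.probability("recovery", age),
            self.probability("death_nd", age),
            self.probability("death_dis", age),
        )


def constant_curves(
    onset: float, recovery: float, death_nd: float, death_dis: float
) -> TransitionCurves:
    """Curves with no age dependence, at the given annual probabilities."""

    def logit(p: float) -> float:
        if p <= 0.0:
            return -745.0  # expit(-745) underflows to exactly 0
        if p >= 1.0:
            return 745.0
        return float(np.log(p / (1.0 - p)))

    return TransitionCurves(
        onset=(logit(onset), 0.0),
        recovery=(logit(recovery), 0.0),
        death_nd=(logit(death_nd), 0.0),
        death_dis=(logit(death_dis), 0.0),
    )


def default_curves() -> dict[tuple[str, str], TransitionCurves]:
    """Realistic operating point for the generator.

    Annual levels are anchored to observed United States panel estimates
    for adults aged 50-70: among people with diabetes, disability onset
    near 6.7/100 person-years, remission near 16/100, mortality 2.9/100
    while non-disabled rising with age, 4.5/100 while disabled; the
    diabetes-free population has roughly one third the onset hazard,
    higher remission and lower mortality.  Men carry slightly higher
    mortality than women (about 0.3 on the logit scale).
    """
    base = {
        "diabetes": {
            "onset": (-2.70, 0.015),
            "recovery": (-1.67, 0.0),
            "death_nd": (-3.90, 0.070),
            "death_dis": (-3.45, 0.070),
        },
        "no_diabetes": {
            "onset": (-3.85, 0.020),
            "recovery": (-1.30, 0.0),
            "death_nd": (-4.70, 0.110),
            "death_dis": (-4.10, 0.110),
        },
    }
    out: dict[tuple[str, str], TransitionCurves] = {}
    for group, curves in base.items():
        for sex in SEXES:
            shift = 0.0 if sex == "male" else -0.30  # women: lower mortality
            out[(sex, group)] = TransitionCurves(
                onset=curves["onset"],
                recovery=curves["recovery"],
                death_nd=(curves["death_nd"][0] + shift, curves["death_nd"][1]),
                death_dis=(curves["death_dis"][0] + shift, curves["death_dis"][1]),
            )
    return out


def default_missingness() -> dict[str, float]:
    """Wave-nonresponse model: logit Pr(respond) given observed history.

    Response depends on age, sex, the previous wave's disability status and
    whether the previous wave was itself answered — a missing-at-random
    mechanism given pair-start covariates, calibrated to follow-up response
    rates around 85-90% that drop for the recently disabled and for prior
    nonresponders.
    """
    return {
        "intercept": 2.4,
        "age": -0.012,  # per year above 50
        "female": 0.10,
        "disabled": -0.80,
        "prior_nonresponse": -1.20,
    }


@dataclass
class SyntheticConfig:
    """All knobs of the generator, with seeds for exact reproducibility."""

    n_persons: int = 2000
    cohort_label: int = 1
    birth_year_range: tuple[int, int] = (1931, 1941)
    baseline_year: int = 1992
    n_waves: int = 6
    curves: Mapping[tuple[str, str], TransitionCurves] = field(default_factory=default_curves)
    diabetes_prevalence: float = 0.10
    diabetes_annual_incidence: float = 0.012
    baseline_disability_prevalence: float = 0.10
    female_share: float = 0.53
    missingness: Mapping[str, float] | None = field(
        default_factory=default_missingness
    )  # None = full response
    weight_sigma: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_waves < 2:
            raise ConfigurationError("n_waves must be at least 2")
        if self.cohort_label not in (1, 2):
            raise ConfigurationError("cohort_label must be 1 or 2")
        lo, hi = self.birth_year_range
        for by in (lo, hi):
            age = self.baseline_year - by
            if not 50 <= age <= 62:
                raise ConfigurationError(
                    f"birth year {by} gives baseline age {age} outside [50, 62]"
                )
        for key in [(s, g) for s in SEXES for g in GROUPS]:
            if key not in self.curves:
                raise ConfigurationError(f"missing transition curves for {key}")
        for key, curves in self.curves.items():
            for name in ("onset", "recovery", "death_nd", "death_dis"):
                for age in range(50, 71):
                    p = curves.probability(name, age)
                    if not 0.0 <= p <= 1.0 or not np.isfinite(p):
                        raise ConfigurationError(
                            f"curve {name} for {key} gives probability {p} at age {age}"
                        )

    def true_probability_fn(self, sex: str, group: str):
        """Age -> annual (onset, recovery, death_nd, death_dis) for a stratum."""
        curves = self.curves[(sex, group)]
        return lambda age: curves.at_age(age)

    def to_json(self) -> str:
        d = asdict(self)
        d["curves"] = {
            f"{sex}|{group}": asdict(c) for (sex, group), c in self.curves.items()
        }
        return json.dumps(d, indent=2, default=list)


def ground_truth_lifetable(
    config: SyntheticConfig, sex: str, diabetes_group: str, baseline_age: int,
    end_age: int = 70,
) -> LifeTableSummary:
    """Life-table summary implied directly by the generating curves.

    Runs the cohort model on the true hazards, bypassing classification and
    estimation entirely — the oracle that recovery tests compare against.
    """
    config.validate()
    spec = MarkovSpec(baseline_age=baseline_age, end_age=end_age)
    traj = run_cohort(spec, config.true_probability_fn(sex, diabetes_group))
    return summarize(traj)


# --- item-pattern machinery -------------------------------------------------

def _patterns_by_count() -> dict[int, np.ndarray]:
    """All 32 five-item difficulty patterns grouped by number of difficulties."""
    pats = np.array(
        [[(i >> b) & 1 for b in range(5)] for i in range(32)], dtype=bool
    )
    counts = pats.sum(axis=1)
    return {k: pats[counts == k] for k in range(6)}


_PATS = _patterns_by_count()
# mobility: disabled = >=4 difficulties; IADL/ADL: disabled = >=1
_MOBILITY_DIS = np.vstack([_PATS[4], _PATS[5]])
_MOBILITY_FREE = np.vstack([_PATS[k] for k in range(4)])
_OTHER_DIS = np.vstack([_PATS[k] for k in range(1, 6)])
_OTHER_FREE = _PATS[0]


def _draw_items(disabled: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw 15 item flags per row so each domain classifies to `disabled`."""
    n = disabled.shape[0]
    items = np.empty((n, 15), dtype=bool)
    for j, (dis_pool, free_pool) in enumerate(
        [(_MOBILITY_DIS, _MOBILITY_FREE), (_OTHER_DIS, _OTHER_FREE), (_OTHER_DIS, _OTHER_FREE)]
    ):
        idx_dis = rng.integers(0, len(dis_pool), size=n)
        idx_free = rng.integers(0, len(free_pool), size=n)
        block = np.where(disabled[:, None], dis_pool[idx_dis], free_pool[idx_free])
        items[:, 5 * j : 5 * (j + 1)] = block
    return items


def simulate_panel(
    config: SyntheticConfig, return_latent: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, np.ndarray]:
    """Generate one long-format panel: one row per person per scheduled wave.

    Every person is followed through all ``n_waves`` scheduled interviews;
    rows after death carry ``alive=False`` with the exact death year.  Item
    and diabetes fields are missing (``NA``) whenever the person did not
    respond at that wave.

    With ``return_latent=True`` also returns the underlying annual state
    array (years x persons, codes as in :mod:`dislife.markov`), which tests
    use to count true annual events directly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons

    lo, hi = config.birth_year_range
    birth_year = rng.integers(lo, hi + 1, size=n)
    baseline_age = config.baseline_year - birth_year
    female = rng.random(n) < config.female_share
    sex = np.where(female, "female", "male")

    n_years = (config.n_waves - 1) * 2
    # diabetes: diagnosed at baseline, or incident during follow-up years
    diag_baseline = rng.random(n) < config.diabetes_prevalence
    diag_year = np.full(n, np.iinfo(np.int32).max, dtype=np.int64)
    diag_year[diag_baseline] = config.baseline_year
    undiag = ~diag_baseline
    for y in range(1, n_years + 1):
        newly = undiag & (rng.random(n) < config.diabetes_annual_incidence)
        diag_year[newly] = config.baseline_year + y
        undiag &= ~newly
    ever_diabetes = diag_year <= config.baseline_year + n_years
    group = np.where(ever_diabetes, "diabetes", "no_diabetes")

    # latent annual five-state walk; ever-diagnosed follow diabetes curves
    states = np.empty((n_years + 1, n), dtype=np.int8)
    start_disabled = rng.random(n) < config.baseline_disability_prevalence
    states[0] = np.where(start_disabled, LTD, ND)
    death_year = np.full(n, -1, dtype=np.int64)
    probs = {
        key: config.curves[key] for key in [(s, g) for s in SEXES for g in GROUPS]
    }
    for y in range(n_years):
        cur = states[y]
        new = cur.copy()
        age = baseline_age + y
        u = rng.random(n)
        p_on = np.empty(n)
        p_rec = np.empty(n)
        p_dnd = np.empty(n)
        p_dd = np.empty(n)
        for (s, g), curves in probs.items():
            mask = (sex == s) & (group == g)
            if not mask.any():
                continue
            a = age[mask]
            p_on[mask] = expit(curves.onset[0] + curves.onset[1] * (a - 50))
            p_rec[mask] = expit(curves.recovery[0] + curves.recovery[1] * (a - 50))
            p_dnd[mask] = expit(curves.death_nd[0] + curves.death_nd[1] * (a - 50))
            p_dd[mask] = expit(curves.death_dis[0] + curves.death_dis[1] * (a - 50))
        nd_like = (cur == ND) | (cur == NDH)
        dis_like = (cur == STD) | (cur == LTD)
        new[nd_like & (u < p_dnd)] = DEAD
        new[nd_like & (u >= p_dnd) & (u < p_dnd + p_on)] = STD
        # survivors without onset keep their non-disabled flavour (ND or NDH)
        new[dis_like & (u < p_dd)] = DEAD
        new[dis_like & (u >= p_dd) & (u < p_dd + p_rec)] = NDH
        new[dis_like & (u >= p_dd + p_rec)] = LTD
        died_now = (cur != DEAD) & (new == DEAD)
        death_year[died_now] = config.baseline_year + y + 1
        states[y + 1] = new

    weights = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=n)
    weights = weights / weights.mean()

    # wave-level response
    miss = config.missingness
    responded = np.ones((config.n_waves, n), dtype=bool)
    if miss is not None:
        for w in range(1, config.n_waves):
            y = 2 * w
            prev_disabled = np.isin(states[y - 2], (STD, LTD))
            lin = (
                miss["intercept"]
                + miss["age"] * (baseline_age + y - 50)
                + miss["female"] * female
                + miss["disabled"] * prev_disabled
                + miss["prior_nonresponse"] * (~responded[w - 1])
            )
            responded[w] = rng.random(n) < expit(lin)
    # a dead person's record is always completed (death-index linkage)
    rows = []
    for w in range(config.n_waves):
        y = 2 * w
        year = config.baseline_year + y
        st = states[y]
        alive = st != DEAD
        resp = responded[w] & alive
        disabled = np.isin(st, (STD, LTD))
        items = _draw_items(disabled, rng)
        diab = diag_year <= year
        df = pd.DataFrame(
            {
                "person_id": np.arange(n),
                "wave": w,
                "interview_year": year,
                "birth_year": birth_year,
                "age": baseline_age + y,
                "sex": sex,
                "sample_weight": weights,
                "alive": alive,
                "death_year": pd.array(
                    np.where(alive, pd.NA, death_year), dtype="Int64"
                ),
                "responded": resp,
                "diabetes": pd.array(np.where(resp, diab, pd.NA), dtype="boolean"),
            }
        )
        for j, col in enumerate(ITEM_COLUMNS):
            df[col] = pd.array(np.where(resp, items[:, j], pd.NA), dtype="boolean")
        rows.append(df)
    panel = pd.concat(rows, ignore_index=True)
    panel = panel.sort_values(["person_id", "wave"], kind="stable").reset_index(drop=True)
    panel = panel[list(PANEL_COLUMNS)]
    if return_latent:
        return panel, states
    return panel


def write_panel(panel: pd.DataFrame, path, config: SyntheticConfig | None = None) -> None:
    """Write panel CSV (UTF-8, NA for missing) plus a JSON config sidecar."""
    panel.to_csv(path, index=False, na_rep="NA")
    if config is not None:
        sidecar = str(path) + ".config.json"
        with open(sidecar, "w", encoding="utf-8") as fh:
            fh.write(config.to_json())


def read_panel(path) -> pd.DataFrame:
    """Read a panel CSV written by :func:`write_panel` (or matching schema)."""
    bool_cols = {c: "boolean" for c in ITEM_COLUMNS}
    bool_cols["diabetes"] = "boolean"
    df = pd.read_csv(path, na_values=["NA"], dtype={"death_year": "Int64"})
    for col, dtype in bool_cols.items():
        df[col] = df[col].astype(dtype)
    for col in ("alive", "responded"):
        df[col] = df[col].astype(bool)
    return df
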