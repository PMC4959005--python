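"""Apply study definitions to a raw panel: disability domains, diabetes
groups, birth-cohort membership, and the person-period expansion that feeds
the discrete-time transition models.

Disability is domain-specific.  Mobility loss means difficulty with at
least four of the five mobility tasks (walking one block, walking several
blocks, one flight of stairs, stooping/crouching/kneeling, pushing or
pulling a large object); IADL and ADL disability mean difficulty with at
least one of the five tasks in the respective domain.  Diabetes is a
fixed person-level group: anyone reporting a diagnosis at any interview
belongs to the diabetes population for their whole record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import DOMAINS, ITEM_COLUMNS

logger = logging.getLogger(__name__)

#: number of item difficulties at or above which a domain counts as disabled
DOMAIN_THRESHOLD = {"mobility": 4, "iadl": 1, "adl": 1}

_DOMAIN_ITEMS = {
    "mobility": [f"mob{i}" for i in range(1, 6)],
    "iadl": [f"iadl{i}" for i in range(1, 6)],
    "adl": [f"adl{i}" for i in range(1, 6)],
}

COHORT_WINDOWS = {1: ((1931, 1941), 1992), 2: ((1942, 1947), 2002)}


class PanelValidationError(ValueError):
    """Raised when a panel violates monotone death or contiguity rules."""


@dataclass(frozen=True)
class DomainStatus:
    """Classification of one domain at one wave."""

    domain: str
    disabled: bool | None  # None = could not be classified (missing items)
    n_difficulties: int | None


def classify_domain(items, domain: str) -> DomainStatus:
    """Apply the threshold rule to five difficulty flags.

    ``items`` is a length-5 sequence of booleans; any missing value (None
    or NA) yields an explicitly missing status, which excludes the wave
    from state classification downstream while still counting it in the
    response-model denominator.
    """
    if domain not in DOMAIN_THRESHOLD:
        raise ValueError(f"unknown domain {domain!r}")
    items = list(items)
    if len(items) != 5:
        raise ValueError(f"expected 5 items for {domain}, got {len(items)}")
    if any(x is None or pd.isna(x) for x in items):
        return DomainStatus(domain=domain, disabled=None, n_difficulties=None)
    n = int(sum(bool(x) for x in items))
    return DomainStatus(
        domain=domain, disabled=n >= DOMAIN_THRESHOLD[domain], n_difficulties=n
    )


def classify_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Add ``<domain>_disabled`` nullable-boolean columns to a panel copy."""
    out = panel.copy()
    for domain, cols in _DOMAIN_ITEMS.items():
        block = out[cols]
        counts = block.sum(axis=1)
        complete = block.notna().all(axis=1)
        status = pd.array(
            np.where(complete, counts >= DOMAIN_THRESHOLD[domain], pd.NA),
            dtype="boolean",
        )
        out[f"{domain}_disabled"] = status
    return out


def assign_diabetes_group(panel: pd.DataFrame) -> pd.Series:
    """Person-level group: 'diabetes' if a diagnosis was ever reported.

    The diagnosis is monotone — reported once, the person belongs to the
    diabetes population for the entire study period, matching the two
    fixed populations the cohort model is run for.
    """
    reported = (panel["diabetes"] == True).to_numpy()  # noqa: E712 (nullable)
    ever = pd.Series(reported, index=panel["person_id"].to_numpy()).groupby(level=0).any()
    return ever.map({True: "diabetes", False: "no_diabetes"}).rename("diabetes_group")


def assign_cohort(birth_year: int, baseline_year: int) -> int | None:
    """Map a birth year / baseline year pair to cohort 1, 2, or None.

    Cohort 1: born 1931-1941, baseline 1992.  Cohort 2: born 1942-1947,
    baseline 2002.  Anything else (including a window/baseline mismatch)
    is excluded with a logged reason.
    """
    for label, ((lo, hi), base) in COHORT_WINDOWS.items():
        if lo <= birth_year <= hi and baseline_year == base:
            return label
    logger.info(
        "excluded: birth year %s with baseline %s matches no cohort window",
        birth_year,
        baseline_year,
    )
    return None


def _validate_panel(panel: pd.DataFrame) -> None:
    df = panel.sort_values(["person_id", "wave"], kind="stable")
    same = df["person_id"].diff() == 0
    alive_jump = df["alive"].astype(int).diff() > 0
    if (same & alive_jump).any():
        bad = sorted(df.loc[same & alive_jump, "person_id"].unique().tolist())
        raise PanelValidationError(f"resurrection (alive after dead) for persons {bad}")
    age_bad = df["age"].diff() != 2
    if (same & age_bad).any():
        bad = sorted(df.loc[same & age_bad, "person_id"].unique().tolist())
        raise PanelValidationError(f"non-contiguous ages for persons {bad}")


def build_person_periods(panel: pd.DataFrame, domain: str) -> pd.DataFrame:
    """Expand a classified panel into wave-pair person-periods for one domain.

    Each row covers one observed two-year interval with the state at its
    start and end.  End states: ``nd`` (non-disabled), ``dis`` (disabled),
    ``dead``.  A pair is emitted when the start wave has an observed domain
    status and either the person died before the next interview (vital
    status is always known) or the end wave also has an observed status;
    pairs whose surviving end wave is unobserved are dropped here and
    reweighted by the response model in the estimator.

    ``baseline_prevalent`` flags persons disabled in this domain at their
    baseline interview; they are excluded from incidence and remission
    estimation downstream.  ``death_year`` carries the exact recorded year
    for intervals ending in death.
    """
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    col = f"{domain}_disabled"
    if col not in panel.columns:
        panel = classify_panel(panel)
    _validate_panel(panel)
    groups = assign_diabetes_group(panel)

    df = panel.sort_values(["person_id", "wave"], kind="stable")
    base = df.groupby("person_id").first()
    baseline_prevalent = base[col] == True  # noqa: E712
    cohort = pd.Series(
        [
            assign_cohort(int(by), int(yr))
            for by, yr in zip(base["birth_year"], base["interview_year"])
        ],
        index=base.index,
    )

    cur = df
    nxt = df.groupby("person_id").shift(-1)
    has_next = nxt["wave"].notna()
    start_ok = cur["alive"] & cur["responded"] & cur[col].notna()
    died = has_next & (nxt["alive"] == False)  # noqa: E712
    end_observed = has_next & (nxt["alive"] == True) & nxt[col].notna()  # noqa: E712
    keep = start_ok & (died | end_observed)

    sub = cur[keep]
    nsub = nxt[keep]
    end_state = np.where(
        nsub["alive"] == False,  # noqa: E712
        "dead",
        np.where(nsub[col].astype("boolean").fillna(False), "dis", "nd"),
    )
    pp = pd.DataFrame(
        {
            "person_id": sub["person_id"].to_numpy(),
            "domain": domain,
            "wave": sub["wave"].to_numpy(),
            "age_start": sub["age"].to_numpy(),
            "interval_years": 2,
            "start_state": np.where(sub[col].astype("boolean"), "dis", "nd"),
            "end_state": end_state,
            "death_year": nsub["death_year"].to_numpy(),
            "sex": sub["sex"].to_numpy(),
            "sample_weight": sub["sample_weight"].to_numpy(),
        }
    )
    pp["diabetes_group"] = pp["person_id"].map(groups)
    pp["cohort"] = pp["person_id"].map(cohort)
    pp["baseline_prevalent"] = (
        pp["person_id"].map(baseline_prevalent).fillna(False).astype(bool)
    )
    # contiguity within person: observed pairs must not overlap (same start
    # wave twice) — guaranteed by construction from a sorted unique panel
    if pp.duplicated(["person_id", "wave"]).any():
        raise PanelValidationError("duplicate person-wave pairs in panel")
    return pp.reset_index(drop=True)
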