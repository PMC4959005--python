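"""Five-state annual-cycle Markov cohort model of disability progression.

The model tracks a closed cohort from a baseline age (50 or 60) to age 70
through five states:

* ``ND``   -- not disabled, no disability history
* ``STD``  -- short-term disabled (disabled for less than one year)
* ``NDH``  -- not disabled, with previous disability
* ``LTD``  -- long-term disabled (disabled more than one year)
* ``DEAD`` -- absorbing

``STD`` and ``NDH`` are one-cycle "bridge" states that distinguish recent
transitions from long-run occupancy: a newly disabled person spends exactly
one cycle in ``STD`` before either recovering (to ``NDH``), dying, or
settling into ``LTD``.  Onset and mortality hazards depend only on the
current disabled / non-disabled status, so ``NDH`` shares ``ND``'s row and
``LTD`` shares ``STD``'s exit probabilities.

Occupancy is counted at cycle start: the person-year for cycle ``t`` is
credited to the state occupied entering it.  This makes the accounting
identity DFY + DY + LYL = horizon exact, and the average onset age equals
baseline age + disability-free years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

STATES = ("ND", "STD", "NDH", "LTD", "DEAD")
ND, STD, NDH, LTD, DEAD = range(5)

#: disability-free states (used for DFY) and disabled states (used for DY)
FREE_STATES = (ND, NDH)
DISABLED_STATES = (STD, LTD)

__all__ = [
    "STATES",
    "MarkovSpec",
    "OccupancyTrajectory",
    "LifeTableSummary",
    "build_transition_matrix",
    "run_cohort",
    "summarize",
    "run_population",
    "microsimulate",
]


class SimplexViolationError(ValueError):
    """Raised when transition probabilities at some age leave a negative remainder."""


@dataclass(frozen=True)
class MarkovSpec:
    """Structure of one cohort run: baseline age, end age and cycle length."""

    baseline_age: int = 50
    end_age: int = 70
    cycle: int = 1

    def __post_init__(self) -> None:
        if self.end_age <= self.baseline_age:
            raise ValueError("end_age must exceed baseline_age")
        if self.cycle != 1:
            raise ValueError("only annual cycles are supported")

    @property
    def horizon(self) -> int:
        """Number of cycles (years) modelled."""
        return self.end_age - self.baseline_age

    @property
    def ages(self) -> np.ndarray:
        """Ages at cycle starts (length = horizon)."""
        return np.arange(self.baseline_age, self.end_age)


@dataclass(frozen=True)
class OccupancyTrajectory:
    """State-occupancy probabilities per cycle, rows indexed 0..horizon."""

    spec: MarkovSpec
    occupancy: np.ndarray  # shape (horizon + 1, 5)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.shape != (self.spec.horizon + 1, 5):
            raise ValueError("occupancy shape does not match spec horizon")
        if (occ < -1e-12).any():
            raise ValueError("negative occupancy mass")
        if np.abs(occ.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("occupancy rows must sum to 1")
        dead = occ[:, DEAD]
        if (np.diff(dead) < -1e-12).any():
            raise ValueError("death mass must be non-decreasing")


@dataclass(frozen=True)
class LifeTableSummary:
    """Expected years by disability status over the modelled horizon.

    ``dfy`` counts years not disabled (including post-recovery years),
    ``dy`` years disabled, ``lyl`` the years of the horizon lost to death,
    ``tle`` the total life expectancy within the horizon, and ``onset_age``
    the average age of disability onset defined as baseline age + DFY.
    """

    baseline_age: int
    horizon: int
    dfy: float
    dy: float
    lyl: float

    @property
    def tle(self) -> float:
        return self.dfy + self.dy

    @property
    def onset_age(self) -> float:
        return self.baseline_age + self.dfy

    def as_dict(self) -> dict[str, float]:
        return {
            "dfy": self.dfy,
            "dy": self.dy,
            "lyl": self.lyl,
            "tle": self.tle,
            "onset_age": self.onset_age,
        }


def build_transition_matrix(
    p_onset: float,
    p_recover: float,
    p_die_nd: float,
    p_die_dis: float,
    *,
    age: int | None = None,
) -> np.ndarray:
    """Assemble the 5x5 annual row-stochastic matrix from the four hazards.

    Rows follow the state order ``ND, STD, NDH, LTD, DEAD``.  A negative
    stay-remainder (onset + death > 1 or recovery + death > 1) raises
    :class:`SimplexViolationError` naming the offending age.
    """
    probs = np.array([p_onset, p_recover, p_die_nd, p_die_dis], dtype=float)
    if (probs < 0).any() or (probs > 1).any():
        raise SimplexViolationError(
            f"transition probabilities outside [0, 1] at age {age}: {probs}"
        )
    stay_nd = 1.0 - p_onset - p_die_nd
    stay_dis = 1.0 - p_recover - p_die_dis
    if stay_nd < -1e-12 or stay_dis < -1e-12:
        raise SimplexViolationError(
            f"probabilities exceed the row simplex at age {age}: "
            f"onset+death_nd={p_onset + p_die_nd:.4f}, "
            f"recover+death_dis={p_recover + p_die_dis:.4f}"
        )
    stay_nd = max(stay_nd, 0.0)
    stay_dis = max(stay_dis, 0.0)
    m = np.zeros((5, 5))
    m[ND] = (stay_nd, p_onset, 0.0, 0.0, p_die_nd)
    m[STD] = (0.0, 0.0, p_recover, stay_dis, p_die_dis)
    m[NDH] = (0.0, p_onset, stay_nd, 0.0, p_die_nd)
    m[LTD] = (0.0, 0.0, p_recover, stay_dis, p_die_dis)
    m[DEAD, DEAD] = 1.0
    return m


ProbFn = Callable[[int], tuple[float, float, float, float]]


def _as_prob_fn(probs) -> ProbFn:
    """Accept a callable age -> 4-tuple or a mapping age -> 4-tuple."""
    if callable(probs):
        return probs
    if isinstance(probs, Mapping):
        return lambda age: probs[age]
    raise TypeError("probs must be callable or a mapping age -> probabilities")


def run_cohort(spec: MarkovSpec, probs) -> OccupancyTrajectory:
    """Propagate a unit mass starting in ``ND`` through the annual model.

    Parameters
    ----------
    spec
        Baseline/end ages of the run.
    probs
        Callable or mapping giving ``(p_onset, p_recover, p_die_nd,
        p_die_dis)`` for each integer age in ``[baseline_age, end_age)``.
    """
    fn = _as_prob_fn(probs)
    occ = np.zeros((spec.horizon + 1, 5))
    occ[0, ND] = 1.0
    v = occ[0]
    for i, age in enumerate(spec.ages):
        try:
            p = fn(int(age))
        except KeyError as exc:
            raise KeyError(f"no transition probabilities for age {age}") from exc
        m = build_transition_matrix(*p, age=int(age))
        v = v @ m
        occ[i + 1] = v
    return OccupancyTrajectory(spec=spec, occupancy=occ)


def summarize(trajectory: OccupancyTrajectory, spec: MarkovSpec | None = None) -> LifeTableSummary:
    """Reduce a trajectory to disability-free / disabled / lost years.

    Person-years for cycle ``t`` are credited to the state occupied at its
    start, so the horizon's cycles are rows ``0 .. horizon-1``.
    """
    spec = spec or trajectory.spec
    occ = trajectory.occupancy[: spec.horizon]
    dfy = float(occ[:, list(FREE_STATES)].sum())
    dy = float(occ[:, list(DISABLED_STATES)].sum())
    lyl = float(spec.horizon - dfy - dy)
    return LifeTableSummary(
        baseline_age=spec.baseline_age, horizon=spec.horizon, dfy=dfy, dy=dy, lyl=lyl
    )


def run_population(
    prob_sets: Mapping,
    baseline_ages: Iterable[int] = (50, 60),
    end_age: int = 70,
) -> dict:
    """Run the cohort model for every stratum in ``prob_sets``.

    ``prob_sets`` maps stratum keys (e.g. ``(sex, group, cohort, domain)``)
    to age-indexed probability lookups; the result maps ``key + (baseline,)``
    to :class:`LifeTableSummary`.
    """
    out = {}
    for key, probs in prob_sets.items():
        for baseline in baseline_ages:
            spec = MarkovSpec(baseline_age=baseline, end_age=end_age)
            traj = run_cohort(spec, probs)
            k = (key if isinstance(key, tuple) else (key,)) + (baseline,)
            out[k] = summarize(traj)
    return out


def microsimulate(
    spec: MarkovSpec,
    probs,
    n_walkers: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Estimate state occupancy by simulating individual annual walks.

    An independent stochastic counterpart to :func:`run_cohort`: each walker
    starts in ``ND`` and samples its own path state-by-state, without ever
    forming the transition matrix product.  Returns occupancy proportions
    with shape ``(horizon + 1, 5)``.
    """
    fn = _as_prob_fn(probs)
    states = np.zeros(n_walkers, dtype=np.int8)  # all start in ND
    counts = np.zeros((spec.horizon + 1, 5))
    counts[0] = np.bincount(states, minlength=5)
    for i, age in enumerate(spec.ages):
        p_on, p_rec, p_dnd, p_dd = fn(int(age))
        u = rng.random(n_walkers)
        new = states.copy()
        nd_like = (states == ND) | (states == NDH)
        dis_like = (states == STD) | (states == LTD)
        # non-disabled: die, become disabled (STD), or stay put
        new[nd_like & (u < p_dnd)] = DEAD
        onset = nd_like & (u >= p_dnd) & (u < p_dnd + p_on)
        new[onset] = STD
        stay_free = nd_like & (u >= p_dnd + p_on)
        # a year spent free of disability: STD history means NDH, else keep state
        new[stay_free & (states == ND)] = ND
        new[stay_free & (states == NDH)] = NDH
        # disabled: die, recover (NDH), or continue disabled (LTD)
        new[dis_like & (u < p_dd)] = DEAD
        new[dis_like & (u >= p_dd) & (u < p_dd + p_rec)] = NDH
        new[dis_like & (u >= p_dd + p_rec)] = LTD
        states = new
        counts[i + 1] = np.bincount(states, minlength=5)
    return counts / n_walkers
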