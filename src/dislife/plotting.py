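"""Plot helpers for occupancy trajectories and fitted probability curves.

Matplotlib is imported lazily so the estimation stack has no hard plotting
dependency; install the ``plot`` extra to use these.
"""

from __future__ import annotations

from .markov import STATES, OccupancyTrajectory
from .transitions import TransitionProbabilitySet

_STATE_LABELS = {
    "ND": "not disabled",
    "STD": "short-term disabled",
    "NDH": "not disabled (history)",
    "LTD": "long-term disabled",
    "DEAD": "dead",
}


def plot_occupancy(trajectory: OccupancyTrajectory, ax=None):
    """Stacked state-occupancy area chart over the modelled ages."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    spec = trajectory.spec
    ages = range(spec.baseline_age, spec.end_age + 1)
    ax.stackplot(
        ages,
        trajectory.occupancy.T,
        labels=[_STATE_LABELS[s] for s in STATES],
        alpha=0.85,
    )
    ax.set_xlabel("age (years)")
    ax.set_ylabel("occupancy probability")
    ax.set_xlim(spec.baseline_age, spec.end_age)
    ax.set_ylim(0, 1)
    ax.legend(loc="center left", fontsize=8)
    return ax


def plot_probability_set(probs: TransitionProbabilitySet, sex: str = "male", ax=None):
    """Annual transition probability curves by age for one sex."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    sub = probs.frame[probs.frame["sex"] == sex].sort_values("age")
    for col, label in [
        ("p_onset", "onset"),
        ("p_recover", "remission"),
        ("p_die_nd", "death, non-disabled"),
        ("p_die_dis", "death, disabled"),
    ]:
        ax.plot(sub["age"], sub[col], label=label)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("annual probability")
    title = f"{probs.domain or 'disability'} ({sex}"
    if probs.diabetes_group:
        title += f", {probs.diabetes_group}"
    ax.set_title(title + ")")
    ax.legend(fontsize=8)
    return ax
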