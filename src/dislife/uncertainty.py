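"""Monte Carlo uncertainty for life-table outputs, contrasts, and report tables.

Parameter uncertainty is propagated by drawing transition-model
coefficient vectors from their asymptotic multivariate normal
distributions (on the logit scale), pushing each draw through the
annualized probability predictions and the five-state cohort model, and
summarizing the resulting ensemble of life tables with percentile
confidence intervals.  Draws are split evenly between the sexes (the
default of 10,000 total means 5,000 per sex).  Differences between
cohorts or diabetes groups use independent ensembles paired by draw
index; two-sided p-values come from the sign distribution of the
per-draw differences, floored at 2/n_draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .markov import LifeTableSummary, MarkovSpec
from .transitions import TransitionResults, _nearest_pd, annualize

logger = logging.getLogger(__name__)

METRICS = ("dfy", "dy", "lyl", "tle", "onset_age")

__all__ = [
    "DrawEnsemble",
    "Contrast",
    "draw_probability_sets",
    "monte_carlo",
    "percentile_ci",
    "contrast",
    "delay_range",
    "percent_change",
    "render_tables",
]


def _draw_params(results: TransitionResults, n_draws: int, rng) -> dict[str, np.ndarray]:
    """Coefficient draws per transition, shape (n_draws, k) each.

    Degenerate (constant-outcome) fits have no sampling distribution: their
    draws are flagged with NaN and the prediction step pins the constant.
    """
    out = {}
    for tr, info in results.fits.items():
        if info.degenerate:
            out[tr] = np.full((n_draws, len(results.param_names)), np.nan)
            continue
        cov = info.cov
        if np.allclose(cov, 0.0):
            out[tr] = np.tile(info.params, (n_draws, 1))
            continue
        out[tr] = rng.multivariate_normal(info.params, _nearest_pd(cov), size=n_draws)
    return out


def _probability_arrays(
    results: TransitionResults,
    param_draws: Mapping[str, np.ndarray],
    ages: np.ndarray,
    female: float,
) -> dict[str, np.ndarray]:
    """Annual probabilities per draw and age, shape (n_draws, n_ages)."""
    k = results.interval_years
    n_draws = next(iter(param_draws.values())).shape[0]
    X = np.column_stack([np.ones(len(ages)), ages - 50.0, np.full(len(ages), female)])
    out = {}
    for tr, draws in param_draws.items():
        info = results.fits[tr]
        if info.degenerate:
            p_int = np.full((n_draws, len(ages)), float(info.constant_value))
        else:
            p_int = expit(draws @ X.T)
        out[tr] = 1.0 - (1.0 - p_int) ** (1.0 / k)
    # proportional simplex clip per draw/age
    for a, b in [("onset", "death_nd"), ("recovery", "death_dis")]:
        total = out[a] + out[b]
        bad = total > 1.0
        if bad.any():
            logger.warning("simplex clip applied to %d draw-age cells", int(bad.sum()))
            scale = np.where(bad, 1.0 / np.where(bad, total, 1.0), 1.0)
            out[a] = out[a] * scale
            out[b] = out[b] * scale
    return out


def draw_probability_sets(
    results: TransitionResults, n_draws: int, seed: int, female: float = 0.0,
    ages=range(50, 70),
) -> dict[str, np.ndarray]:
    """Random annual probability curves for one sex: transition -> (n_draws, n_ages)."""
    rng = np.random.default_rng(seed)
    ages = np.asarray(list(ages), dtype=float)
    return _probability_arrays(results, _draw_params(results, n_draws, rng), ages, female)


def _run_engine_batch(
    probs: Mapping[str, np.ndarray], baseline_age: int, end_age: int, ages: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized cohort run across draws; returns metric arrays per draw.

    Matches :func:`dislife.markov.run_cohort` + ``summarize`` exactly, with
    the occupancy update unrolled over the five states.
    """
    sel = (ages >= baseline_age) & (ages < end_age)
    on = probs["onset"][:, sel]
    rec = probs["recovery"][:, sel]
    dnd = probs["death_nd"][:, sel]
    dd = probs["death_dis"][:, sel]
    n_draws, horizon = on.shape
    v = np.zeros((n_draws, 5))
    v[:, 0] = 1.0
    dfy = np.zeros(n_draws)
    dy = np.zeros(n_draws)
    for t in range(horizon):
        dfy += v[:, 0] + v[:, 2]
        dy += v[:, 1] + v[:, 3]
        o, r, q, s = on[:, t], rec[:, t], dnd[:, t], dd[:, t]
        nd_mass = v[:, 0]
        std_mass = v[:, 1]
        ndh_mass = v[:, 2]
        ltd_mass = v[:, 3]
        dis_mass = std_mass + ltd_mass
        v = np.column_stack(
            [
                nd_mass * (1.0 - o - q),
                (nd_mass + ndh_mass) * o,
                ndh_mass * (1.0 - o - q) + dis_mass * r,
                dis_mass * (1.0 - r - s),
                v[:, 4] + (nd_mass + ndh_mass) * q + dis_mass * s,
            ]
        )
    lyl = horizon - dfy - dy
    return {
        "dfy": dfy,
        "dy": dy,
        "lyl": lyl,
        "tle": dfy + dy,
        "onset_age": baseline_age + dfy,
    }


@dataclass
class DrawEnsemble:
    """Monte Carlo life-table draws for one fitted stratum.

    ``draws[(sex, baseline_age)]`` maps metric names to per-draw arrays;
    ``points[(sex, baseline_age)]`` holds the point-estimate life table.
    """

    n_draws: int
    seed: int
    draws: dict = field(default_factory=dict)
    points: dict = field(default_factory=dict)

    def metric(self, sex: str, baseline_age: int, name: str) -> np.ndarray:
        return self.draws[(sex, baseline_age)][name]

    def point(self, sex: str, baseline_age: int) -> LifeTableSummary:
        return self.points[(sex, baseline_age)]

    def ci(self, sex: str, baseline_age: int, name: str, level: float = 0.95):
        return percentile_ci(self.metric(sex, baseline_age, name), level)

    def summary_frame(self, level: float = 0.95) -> pd.DataFrame:
        rows = []
        for (sex, baseline), point in sorted(self.points.items()):
            rec = {"sex": sex, "baseline_age": baseline}
            for m in METRICS:
                lo, hi = self.ci(sex, baseline, m, level)
                rec[m] = getattr(point, m)
                rec[f"{m}_low"] = lo
                rec[f"{m}_high"] = hi
            rows.append(rec)
        return pd.DataFrame(rows)


def monte_carlo(
    results: TransitionResults,
    n_draws: int = 10_000,
    seed: int = 0,
    baseline_ages=(50, 60),
    end_age: int = 70,
) -> DrawEnsemble:
    """Build the Monte Carlo ensemble for a fitted transition model.

    ``n_draws`` is the total across sexes (half per sex).  A fixed seed
    reproduces the ensemble exactly.
    """
    per_sex = n_draws // 2
    if per_sex < 1:
        raise ValueError("n_draws must be at least 2")
    ages = np.arange(50, end_age, dtype=float)
    ens = DrawEnsemble(n_draws=per_sex * 2, seed=seed)
    rng = np.random.default_rng(seed)
    for sex, fem in (("male", 0.0), ("female", 1.0)):
        param_draws = _draw_params(results, per_sex, rng)
        probs = _probability_arrays(results, param_draws, ages, fem)
        for baseline in baseline_ages:
            ens.draws[(sex, baseline)] = _run_engine_batch(
                probs, baseline, end_age, ages
            )
            ens.points[(sex, baseline)] = results.life_table(baseline, sex, end_age)
    return ens


def percentile_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval of a draw ensemble (needs >= 100 draws)."""
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise ValueError(f"need at least 100 draws for a percentile CI, got {values.size}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(values, [100.0 * alpha, 100.0 * (1.0 - alpha)])
    return float(lo), float(hi)


@dataclass(frozen=True)
class Contrast:
    """Difference of one life-table metric between two ensembles (B - A)."""

    metric: str
    sex: str
    baseline_age: int
    difference: float
    ci_low: float
    ci_high: float
    p_value: float


def contrast(
    ensemble_a: DrawEnsemble,
    ensemble_b: DrawEnsemble,
    metric: str,
    sex: str,
    baseline_age: int,
    level: float = 0.95,
) -> Contrast:
    """B minus A: point difference, percentile CI, and a sign-based p-value.

    Ensembles are independent (fitted on disjoint samples) and are paired
    by draw index; equal draw counts are required.  The two-sided p-value
    is ``2 * min(share of differences >= 0, share <= 0)``, clipped to 1 and
    floored at ``2 / n_draws``.
    """
    a = ensemble_a.metric(sex, baseline_age, metric)
    b = ensemble_b.metric(sex, baseline_age, metric)
    if a.shape != b.shape:
        raise ValueError("mismatched draw counts between ensembles")
    if ensemble_a is not ensemble_b and ensemble_a.seed == ensemble_b.seed:
        logger.warning(
            "contrast between ensembles with identical seeds: common random "
            "numbers collapse the draw variance of the difference and make "
            "p-values anticonservative; use distinct seeds"
        )
    d = b - a
    point = getattr(ensemble_b.point(sex, baseline_age), metric) - getattr(
        ensemble_a.point(sex, baseline_age), metric
    )
    lo, hi = percentile_ci(d, level)
    n = d.size
    p = 2.0 * min(float(np.mean(d >= 0)), float(np.mean(d <= 0)))
    p = min(1.0, max(p, 2.0 / n))
    return Contrast(
        metric=metric,
        sex=sex,
        baseline_age=baseline_age,
        difference=float(point),
        ci_low=lo,
        ci_high=hi,
        p_value=p,
    )


def delay_range(
    onset_cohort1: Mapping[str, float], onset_cohort2: Mapping[str, float]
) -> tuple[float, float]:
    """Min and max cohort-2 minus cohort-1 onset-age delay across domains.

    Both mappings must cover the same three disability domains.
    """
    if set(onset_cohort1) != set(onset_cohort2):
        raise ValueError("cohorts must cover the same domains")
    if not onset_cohort1:
        raise ValueError("no domains supplied")
    delays = [onset_cohort2[d] - onset_cohort1[d] for d in onset_cohort1]
    return (min(delays), max(delays))


def percent_change(baseline: float, followup: float) -> int:
    """Percent change from baseline, rounded to an integer for reporting."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return int(round((followup - baseline) / baseline * 100.0))


def _fmt(x: float, lo: float, hi: float) -> str:
    return f"{x:.1f} ({lo:.1f},{hi:.1f})"


def render_tables(
    summaries: Mapping,
    contrasts=(),
    outdir: str | Path = ".",
    level: float = 0.95,
) -> list[Path]:
    """Write per-sex life-table report files plus a contrast annex.

    ``summaries`` maps ``(sex, diabetes_group, cohort, domain, baseline_age)``
    to a :class:`DrawEnsemble` (whose point and CI are used).  Outputs one
    CSV and one aligned plain-text table per sex, and ``contrasts.csv``.
    Rendering is deterministic: identical inputs give identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    by_sex: dict[str, list[dict]] = {}
    for (sex, group, cohort, domain, baseline), ens in sorted(summaries.items()):
        point = ens.point(sex, baseline)
        rec = {
            "diabetes_group": group,
            "cohort": cohort,
            "domain": domain,
            "baseline_age": baseline,
        }
        for m in METRICS:
            lo, hi = ens.ci(sex, baseline, m, level)
            rec[m] = getattr(point, m)
            rec[f"{m}_low"] = lo
            rec[f"{m}_high"] = hi
        by_sex.setdefault(sex, []).append(rec)
    for sex, rows in sorted(by_sex.items()):
        df = pd.DataFrame(rows).sort_values(
            ["diabetes_group", "cohort", "domain", "baseline_age"]
        )
        csv_path = outdir / f"lifetable_{sex}.csv"
        df.to_csv(csv_path, index=False, float_format="%.4f")
        written.append(csv_path)
        txt_path = outdir / f"lifetable_{sex}.txt"
        lines = [
            f"Estimated healthy and disabled years ({sex}), baseline age to 70",
            f"{'group':<12}{'cohort':>7}{'domain':>10}{'age':>5}"
            f"{'DFY':>18}{'DY':>18}{'LYL':>18}{'onset age':>20}",
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r['diabetes_group']:<12}{r['cohort']:>7}{r['domain']:>10}"
                f"{r['baseline_age']:>5}"
                f"{_fmt(r['dfy'], r['dfy_low'], r['dfy_high']):>18}"
                f"{_fmt(r['dy'], r['dy_low'], r['dy_high']):>18}"
                f"{_fmt(r['lyl'], r['lyl_low'], r['lyl_high']):>18}"
                f"{_fmt(r['onset_age'], r['onset_age_low'], r['onset_age_high']):>20}"
            )
        txt_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(txt_path)
    if contrasts:
        cdf = pd.DataFrame([c.__dict__ for c in contrasts])
        cpath = outdir / "contrasts.csv"
        cdf.to_csv(cpath, index=False, float_format="%.4f")
        written.append(cpath)
    return written
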