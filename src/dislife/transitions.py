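"""Discrete-time transition probability estimation from biennial panels.

The estimand is the set of *annual* age-specific probabilities of
disability onset, remission, and death by disability state for each
sex x diabetes-group x cohort x domain.  Waves are two years apart, so
each model is a pooled logistic regression on wave-pair person-periods
(logit-linear in age with a sex main effect), with cluster-robust
standard errors by person — the working-independence GEE: point
estimates equal the pooled logistic fit and the variance is robust to
within-person correlation.  Fitted two-year probabilities are converted
to annual ones by the constant-hazard complement-root convention
``p_1 = 1 - (1 - p_k)**(1/k)``.

Attrition is handled by inverse-probability weighting: a logistic model
of wave response given age, sex, the previous wave's disability status
and prior response supplies weights ``1/p_hat`` for complete survivor
pairs.  Intervals ending in death need no reweighting because vital
status is always recorded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit as _logit

from .cohort import build_person_periods, classify_panel
from .markov import LifeTableSummary, MarkovSpec, run_cohort, summarize
from .synthetic import DOMAINS, GROUPS, SEXES

logger = logging.getLogger(__name__)

TRANSITIONS = ("onset", "recovery", "death_nd", "death_dis")

__all__ = [
    "annualize",
    "fit_ipw",
    "IPWModel",
    "TransitionModel",
    "TransitionResults",
    "TransitionProbabilitySet",
    "grouped_annual_rates",
    "TRANSITIONS",
]


def annualize(p, k: float):
    """Convert a k-year transition probability to an annual one.

    Assumes a constant hazard within the interval: ``1 - (1-p)**(1/k)``.
    ``p = 1`` maps to 1 for any k.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probability outside [0, 1]")
    if k < 1:
        raise ValueError("interval length must be >= 1 year")
    out = 1.0 - (1.0 - p) ** (1.0 / k)
    return float(out) if out.ndim == 0 else out


# --- inverse-probability-of-response weights --------------------------------

@dataclass
class IPWModel:
    """Fitted logistic model of Pr(complete data at wave | covariates)."""

    params: np.ndarray
    param_names: list[str]
    fitted: bool
    #: per (person_id, wave): predicted response probability
    _phat: pd.Series = field(repr=False, default=None)

    def response_probability(self, person_id, wave) -> pd.Series:
        """Predicted completeness probability for given person-waves."""
        idx = pd.MultiIndex.from_arrays([person_id, wave])
        return pd.Series(self._phat.reindex(idx).to_numpy(), index=range(len(idx)))

    def weight(self, person_id, wave) -> np.ndarray:
        """IPW weight 1/p_hat; 1 where the wave was outside the model (baseline)."""
        p = self._phat.reindex(
            pd.MultiIndex.from_arrays([person_id, wave])
        ).to_numpy()
        p = np.where(np.isnan(p), 1.0, p)
        return 1.0 / p


def _carry_forward_disabled(panel: pd.DataFrame, status_col: str) -> pd.Series:
    """Last observed domain status per person, shifted to the current wave."""
    df = panel.sort_values(["person_id", "wave"], kind="stable")
    obs = df[status_col].astype("boolean")
    filled = obs.groupby(df["person_id"]).ffill().fillna(False)
    lagged = filled.groupby(df["person_id"]).shift(1).astype("boolean")
    return lagged.reindex(panel.index)


def fit_ipw(panel: pd.DataFrame, domain: str = "mobility") -> IPWModel:
    """Fit the wave-response model on all living follow-up person-waves.

    Covariates: age (centred at 50), sex, previous wave's disability
    status in ``domain`` (last observed, carried forward), and whether the
    previous wave was answered.  If every wave is complete the model is
    degenerate and all weights are exactly 1.
    """
    status_col = f"{domain}_disabled"
    if status_col not in panel.columns:
        panel = classify_panel(panel)
    df = panel.sort_values(["person_id", "wave"], kind="stable").reset_index(drop=True)
    prev_responded = (
        df.groupby("person_id")["responded"]
        .shift(1)
        .astype("boolean")
        .fillna(True)
        .astype(bool)
    )
    prev_disabled = _carry_forward_disabled(df, status_col).fillna(False).astype(bool)
    mask = (df["wave"] >= 1) & df["alive"]
    y = df.loc[mask, "responded"].astype(float).to_numpy()
    X = np.column_stack(
        [
            np.ones(mask.sum()),
            df.loc[mask, "age"].to_numpy(dtype=float) - 50.0,
            (df.loc[mask, "sex"] == "female").to_numpy(dtype=float),
            prev_disabled[mask].to_numpy(dtype=float),
            (~prev_responded[mask]).to_numpy(dtype=float),
        ]
    )
    names = ["const", "age_c", "female", "prev_disabled", "prior_nonresponse"]
    if y.min() == y.max():
        phat = np.full(len(y), float(y.max()) if y.max() > 0 else 1.0)
        params = np.zeros(X.shape[1])
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            params = np.asarray(res.params)
            if not np.isfinite(params).all():
                raise ValueError("non-finite response-model coefficients")
        except Exception:
            logger.warning("response model separation; falling back to penalized fit")
            res = sm.Logit(y, X).fit_regularized(alpha=1e-4, disp=0)
            params = np.asarray(res.params)
        phat = expit(X @ params)
    phat = np.clip(phat, 1e-6, 1.0)
    series = pd.Series(
        phat,
        index=pd.MultiIndex.from_arrays(
            [df.loc[mask, "person_id"], df.loc[mask, "wave"]]
        ),
    )
    return IPWModel(params=params, param_names=names, fitted=True, _phat=series)


# --- transition models ------------------------------------------------------

@dataclass
class _FitInfo:
    params: np.ndarray  # (const, age_c, female) on the interval-logit scale
    cov: np.ndarray
    n_obs: int
    n_events: int
    degenerate: bool  # constant-outcome stratum (zero or one everywhere)
    constant_value: float | None = None


def _fit_binomial(y, X, weights, groups) -> _FitInfo:
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    events = int(round(y.sum()))
    if n == 0 or y.min() == y.max():
        # no events (or all events): probability pinned with infinite variance
        const = float(y.max()) if n else 0.0
        logger.warning(
            "constant outcome (%d obs, %d events): probability fixed at %s "
            "with infinite-variance flag",
            n,
            events,
            const,
        )
        return _FitInfo(
            params=np.full(k, np.nan),
            cov=np.full((k, k), np.inf),
            n_obs=n,
            n_events=events,
            degenerate=True,
            constant_value=const,
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=weights)
            res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(groups)})
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        if not (np.isfinite(params).all() and np.isfinite(cov).all()):
            raise ValueError("non-finite estimates")
    except Exception:
        logger.warning("separation in transition model; penalized fallback")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit_regularized(alpha=1e-4, disp=0)
            params = np.asarray(res.params)
            # expected-information covariance at the penalized solution
            p = expit(X @ params)
            w = np.asarray(weights) * p * (1 - p)
            info = X.T @ (X * w[:, None]) + 1e-4 * np.eye(k)
            cov = np.linalg.inv(info)
    return _FitInfo(
        params=params, cov=cov, n_obs=n, n_events=events, degenerate=False
    )


@dataclass(frozen=True)
class TransitionProbabilitySet:
    """Annual transition probabilities per integer age and sex, one stratum.

    Backed by a wide DataFrame with columns ``age, sex, p_onset,
    p_recover, p_die_nd, p_die_dis`` plus ``se_logit_*`` columns (standard
    errors of the interval-scale logits).  Probabilities respect the row
    simplex (onset + death <= 1, recovery + death <= 1); violations are
    clipped proportionally at construction with a logged warning.
    """

    frame: pd.DataFrame
    domain: str = ""
    diabetes_group: str = ""
    cohort: int | None = None

    @staticmethod
    def clip_simplex(frame: pd.DataFrame) -> pd.DataFrame:
        frame = frame.copy()
        for a, b in [("p_onset", "p_die_nd"), ("p_recover", "p_die_dis")]:
            total = frame[a] + frame[b]
            bad = total > 1.0
            if bad.any():
                logger.warning(
                    "simplex violation in %d rows (%s + %s > 1); clipped proportionally",
                    int(bad.sum()),
                    a,
                    b,
                )
                scale = np.where(bad, 1.0 / total, 1.0)
                frame[a] = frame[a] * scale
                frame[b] = frame[b] * scale
        return frame

    def prob_fn(self, sex: str):
        """Age -> (p_onset, p_recover, p_die_nd, p_die_dis) for one sex."""
        sub = self.frame[self.frame["sex"] == sex].set_index("age")
        table = {
            int(age): (
                float(row["p_onset"]),
                float(row["p_recover"]),
                float(row["p_die_nd"]),
                float(row["p_die_dis"]),
            )
            for age, row in sub.iterrows()
        }

        def fn(age: int):
            if age not in table:
                raise KeyError(f"no probabilities for age {age}")
            return table[age]

        return fn

    def to_tidy(self) -> pd.DataFrame:
        """Long format: age, sex, group, cohort, domain, transition, p, se_logit."""
        rows = []
        names = {
            "onset": "p_onset",
            "recovery": "p_recover",
            "death_nd": "p_die_nd",
            "death_dis": "p_die_dis",
        }
        for tr, col in names.items():
            sub = self.frame[["age", "sex", col, f"se_logit_{tr}"]].copy()
            sub.columns = ["age", "sex", "p", "se_logit"]
            sub.insert(2, "transition", tr)
            rows.append(sub)
        out = pd.concat(rows, ignore_index=True)
        out.insert(2, "domain", self.domain)
        out.insert(2, "cohort", self.cohort)
        out.insert(2, "diabetes_group", self.diabetes_group)
        return out

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame) -> "TransitionProbabilitySet":
        names = {
            "onset": "p_onset",
            "recovery": "p_recover",
            "death_nd": "p_die_nd",
            "death_dis": "p_die_dis",
        }
        wide = None
        for tr, col in names.items():
            sub = tidy[tidy["transition"] == tr][["age", "sex", "p", "se_logit"]]
            sub = sub.rename(columns={"p": col, "se_logit": f"se_logit_{tr}"})
            wide = sub if wide is None else wide.merge(sub, on=["age", "sex"])
        meta = tidy.iloc[0]
        return cls(
            frame=wide,
            domain=str(meta.get("domain", "")),
            diabetes_group=str(meta.get("diabetes_group", "")),
            cohort=None if pd.isna(meta.get("cohort")) else int(meta["cohort"]),
        )


class TransitionModel:
    """Pooled-logistic transition model for one domain / group / cohort stratum.

    Build with :meth:`from_panel` (raw long panel) or :meth:`from_person_periods`
    (a pre-built person-period table); :meth:`fit` returns
    :class:`TransitionResults`.
    """

    def __init__(
        self,
        person_periods: pd.DataFrame,
        domain: str,
        diabetes_group: str | None = None,
        cohort: int | None = None,
    ):
        pp = person_periods
        if diabetes_group is not None:
            pp = pp[pp["diabetes_group"] == diabetes_group]
        if cohort is not None:
            pp = pp[pp["cohort"] == cohort]
        if "weight" not in pp.columns:
            pp = pp.assign(weight=pp["sample_weight"].to_numpy(dtype=float))
        self.person_periods = pp.reset_index(drop=True)
        self.domain = domain
        self.diabetes_group = diabetes_group
        self.cohort = cohort
        ks = self.person_periods["interval_years"].unique()
        if len(ks) > 1:
            raise ValueError("mixed interval lengths are not supported in one fit")
        self.interval_years = int(ks[0]) if len(ks) else 2

    # ---- constructors ----
    @classmethod
    def from_panel(
        cls,
        panel: pd.DataFrame,
        domain: str,
        diabetes_group: str | None = None,
        cohort: int | None = None,
        ipw: bool = True,
    ) -> "TransitionModel":
        """Classify a raw panel, expand person-periods, and attach weights.

        The analysis weight of a survivor pair is the sampling weight times
        the inverse probability that its end wave was answered; pairs ending
        in death keep the sampling weight (deaths are always recorded).
        """
        classified = classify_panel(panel)
        pp = build_person_periods(classified, domain)
        if diabetes_group is not None:
            pp = pp[pp["diabetes_group"] == diabetes_group].reset_index(drop=True)
        if cohort is not None:
            pp = pp[pp["cohort"] == cohort].reset_index(drop=True)
        w = pp["sample_weight"].to_numpy(dtype=float).copy()
        if ipw:
            model = fit_ipw(classified, domain)
            end_wave = pp["wave"].to_numpy() + 1
            ipw_w = model.weight(pp["person_id"].to_numpy(), end_wave)
            survivor = (pp["end_state"] != "dead").to_numpy()
            w = np.where(survivor, w * ipw_w, w)
        pp = pp.assign(weight=w)
        return cls(pp, domain, diabetes_group, cohort)

    @classmethod
    def from_person_periods(cls, person_periods: pd.DataFrame, domain: str, **kw):
        return cls(person_periods, domain, **kw)

    # ---- fitting ----
    def _design(self, sub: pd.DataFrame) -> np.ndarray:
        return np.column_stack(
            [
                np.ones(len(sub)),
                sub["age_start"].to_numpy(dtype=float) - 50.0,
                (sub["sex"] == "female").to_numpy(dtype=float),
            ]
        )

    def fit(self) -> "TransitionResults":
        pp = self.person_periods
        fits: dict[str, _FitInfo] = {}
        subsets = {
            # onset & death among the non-disabled; incidence excludes the
            # baseline-prevalent, and onset conditions on surviving the pair
            "onset": pp[
                (pp["start_state"] == "nd")
                & ~pp["baseline_prevalent"]
                & (pp["end_state"] != "dead")
            ],
            "death_nd": pp[pp["start_state"] == "nd"],
            "recovery": pp[
                (pp["start_state"] == "dis")
                & ~pp["baseline_prevalent"]
                & (pp["end_state"] != "dead")
            ],
            "death_dis": pp[pp["start_state"] == "dis"],
        }
        outcomes = {
            "onset": lambda s: (s["end_state"] == "dis"),
            "death_nd": lambda s: (s["end_state"] == "dead"),
            "recovery": lambda s: (s["end_state"] == "nd"),
            "death_dis": lambda s: (s["end_state"] == "dead"),
        }
        for name, sub in subsets.items():
            y = outcomes[name](sub).to_numpy(dtype=float)
            X = self._design(sub)
            w = sub["weight"].to_numpy(dtype=float)
            if len(w) and w.sum() > 0:
                w = w * (len(w) / w.sum())  # normalize to the analytic sample size
            fits[name] = _fit_binomial(y, X, w, sub["person_id"].to_numpy())
        if len(pp):
            age_range = (
                float(pp["age_start"].min()),
                float(pp["age_start"].max()) + self.interval_years,
            )
        else:
            age_range = (50.0, 70.0)
        return TransitionResults(
            fits=fits,
            domain=self.domain,
            diabetes_group=self.diabetes_group,
            cohort=self.cohort,
            interval_years=self.interval_years,
            param_names=["const", "age_c", "female"],
            age_support=age_range,
        )


@dataclass
class TransitionResults:
    """Fitted coefficient sets (interval-logit scale) with robust covariance."""

    fits: dict[str, _FitInfo]
    domain: str
    diabetes_group: str | None
    cohort: int | None
    interval_years: int
    param_names: list[str]
    age_support: tuple[float, float] = (50.0, 70.0)

    def params(self, transition: str) -> np.ndarray:
        return self.fits[transition].params

    def cov_params(self, transition: str) -> np.ndarray:
        return self.fits[transition].cov

    # ---- prediction ----
    def _interval_probability(
        self, transition: str, ages: np.ndarray, female: float,
        params: np.ndarray | None = None,
    ) -> np.ndarray:
        info = self.fits[transition]
        if info.degenerate:
            return np.full(len(ages), float(info.constant_value))
        b = info.params if params is None else params
        X = np.column_stack(
            [np.ones(len(ages)), ages - 50.0, np.full(len(ages), female)]
        )
        return expit(X @ b)

    def predict_probability_set(
        self,
        ages=range(50, 71),
        params_override: dict[str, np.ndarray] | None = None,
    ) -> TransitionProbabilitySet:
        """Annualized predictions at each integer age for both sexes.

        Ages outside the fitted person-periods' support are extrapolations
        of the logit-linear model (a warning is logged once per call).
        """
        ages = np.asarray(list(ages), dtype=float)
        lo, hi = self.age_support
        if ages.min() < lo or ages.max() > hi:
            logger.warning(
                "predicting outside fitted age support [%s, %s]: extrapolating",
                lo,
                hi,
            )
        rows = []
        k = self.interval_years
        over = params_override or {}
        for sex, fem in (("male", 0.0), ("female", 1.0)):
            rec = {"age": ages.astype(int), "sex": sex}
            for tr, col in [
                ("onset", "p_onset"),
                ("recovery", "p_recover"),
                ("death_nd", "p_die_nd"),
                ("death_dis", "p_die_dis"),
            ]:
                p_int = self._interval_probability(tr, ages, fem, over.get(tr))
                rec[col] = annualize(p_int, k)
                info = self.fits[tr]
                if info.degenerate:
                    se = np.full(len(ages), np.inf if info.n_obs else np.nan)
                else:
                    X = np.column_stack(
                        [np.ones(len(ages)), ages - 50.0, np.full(len(ages), fem)]
                    )
                    se = np.sqrt(np.einsum("ij,jk,ik->i", X, info.cov, X))
                rec[f"se_logit_{tr}"] = se
            rows.append(pd.DataFrame(rec))
        frame = pd.concat(rows, ignore_index=True)
        frame = TransitionProbabilitySet.clip_simplex(frame)
        return TransitionProbabilitySet(
            frame=frame,
            domain=self.domain,
            diabetes_group=self.diabetes_group or "",
            cohort=self.cohort,
        )

    # ---- downstream conveniences ----
    def life_table(
        self, baseline_age: int, sex: str, end_age: int = 70
    ) -> LifeTableSummary:
        """Point-estimate life table from the fitted probabilities."""
        probs = self.predict_probability_set(range(50, end_age + 1))
        spec = MarkovSpec(baseline_age=baseline_age, end_age=end_age)
        return summarize(run_cohort(spec, probs.prob_fn(sex)))

    def monte_carlo(self, n_draws: int = 10_000, seed: int = 0, **kw):
        """Monte Carlo ensemble of life tables (see :mod:`dislife.uncertainty`)."""
        from .uncertainty import monte_carlo

        return monte_carlo(self, n_draws=n_draws, seed=seed, **kw)

    def summary(self) -> str:
        """Human-readable coefficient table, one block per transition."""
        lines = [
            "Disability transition model "
            f"(domain={self.domain}, group={self.diabetes_group}, "
            f"cohort={self.cohort}, interval={self.interval_years}y)",
            "=" * 76,
            f"{'transition':<12}{'term':<20}{'coef':>10}{'robust se':>12}"
            f"{'n':>8}{'events':>8}",
            "-" * 76,
        ]
        for tr in TRANSITIONS:
            info = self.fits[tr]
            if info.degenerate:
                lines.append(
                    f"{tr:<12}{'(constant outcome)':<20}"
                    f"{info.constant_value!s:>10}{'inf':>12}"
                    f"{info.n_obs:>8}{info.n_events:>8}"
                )
                continue
            se = np.sqrt(np.diag(info.cov))
            for j, name in enumerate(self.param_names):
                lines.append(
                    f"{tr:<12}{name:<20}{info.params[j]:>10.4f}{se[j]:>12.4f}"
                    f"{info.n_obs:>8}{info.n_events:>8}"
                )
        lines.append("=" * 76)
        return "\n".join(lines)


# --- grouped annual rates (Table-2 style) ------------------------------------

_AGE_BANDS = {"50-60": (50, 60), "61-70": (61, 70), "total": (50, 70)}


def grouped_annual_rates(
    person_periods: pd.DataFrame,
    domain: str,
    n_draws: int = 500,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Sex-adjusted annual event rates per 100 person-years by age band.

    For each diabetes group x cohort present in the table, reports annual
    disability incidence (among the non-prevalent non-disabled), remission
    (among the incident disabled) and mortality among the disabled, for
    ages 50-60, 61-70 and overall.  Adjustment for sex uses predicted
    margins: each person-period's predicted annual probability is averaged
    with sex set to male and female, weighted by the pooled sex
    distribution.  Confidence intervals come from normal draws of the
    model coefficients.  Empty cells yield NA with a log entry.
    """
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0
    pooled_female = float(
        np.average(
            (person_periods["sex"] == "female").to_numpy(dtype=float),
            weights=person_periods["weight"].to_numpy(dtype=float)
            if "weight" in person_periods
            else None,
        )
    )
    out = []
    strata = person_periods.groupby(["diabetes_group", "cohort"], dropna=False)
    for (group, cohort), sub in strata:
        model = TransitionModel(sub, domain, None, None)
        res = model.fit()
        k = model.interval_years
        for tr, label in [
            ("onset", "incidence"),
            ("recovery", "recovery"),
            ("death_dis", "mortality_disabled"),
        ]:
            info = res.fits[tr]
            base = {
                "onset": sub[
                    (sub["start_state"] == "nd")
                    & ~sub["baseline_prevalent"]
                    & (sub["end_state"] != "dead")
                ],
                "recovery": sub[
                    (sub["start_state"] == "dis")
                    & ~sub["baseline_prevalent"]
                    & (sub["end_state"] != "dead")
                ],
                "death_dis": sub[sub["start_state"] == "dis"],
            }[tr]
            for band, (lo, hi) in _AGE_BANDS.items():
                rows = base[(base["age_start"] >= lo) & (base["age_start"] <= hi)]
                if len(rows) == 0 or info.degenerate and info.n_obs == 0:
                    logger.warning(
                        "empty cell: %s %s cohort %s band %s", domain, group, cohort, band
                    )
                    out.append(
                        {
                            "domain": domain,
                            "diabetes_group": group,
                            "cohort": cohort,
                            "measure": label,
                            "age_band": band,
                            "rate_per_100py": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "n_periods": 0,
                        }
                    )
                    continue
                ages = rows["age_start"].to_numpy(dtype=float)
                w = (
                    rows["weight"].to_numpy(dtype=float)
                    if "weight" in rows
                    else np.ones(len(rows))
                )

                def margin(params=None):
                    pm = annualize(
                        res._interval_probability(tr, ages, 0.0, params), k
                    )
                    pf = annualize(
                        res._interval_probability(tr, ages, 1.0, params), k
                    )
                    p = (1.0 - pooled_female) * pm + pooled_female * pf
                    return float(np.average(p, weights=w)) * 100.0

                point = margin()
                if info.degenerate:
                    lo_ci, hi_ci = (point, point) if info.constant_value == 0 else (np.nan, np.nan)
                else:
                    draws = rng.multivariate_normal(
                        info.params, _nearest_pd(info.cov), size=n_draws
                    )
                    vals = np.array([margin(d) for d in draws])
                    lo_ci, hi_ci = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
                out.append(
                    {
                        "domain": domain,
                        "diabetes_group": group,
                        "cohort": cohort,
                        "measure": label,
                        "age_band": band,
                        "rate_per_100py": point,
                        "ci_low": lo_ci,
                        "ci_high": hi_ci,
                        "n_periods": len(rows),
                    }
                )
    return pd.DataFrame(out)


def _nearest_pd(cov: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Clip eigenvalues so the covariance is positive definite."""
    cov = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() >= eps:
        return cov
    logger.warning("covariance not positive definite; eigenvalues clipped")
    vals = np.clip(vals, eps, None)
    return vecs @ np.diag(vals) @ vecs.T
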