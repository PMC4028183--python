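"""Gene–lifestyle interaction estimation with family-wise error control.

Interaction parameters (score-by-factor or SNP-by-factor) are estimated
within each country by adding a product term to the Prentice-weighted Cox
model, pooled across countries by DerSimonian–Laird random effects, and
tested by a Wald test on the pooled estimate.  Bonferroni-adjusted
thresholds control the family-wise error rate over the configured test
family (seven lifestyle factors for the score: sex, family history, BMI,
waist circumference, baseline age, physical activity, diet score).
Stratified hazard ratios by factor level and analyses with cases grouped by
age at diagnosis round out the module.

Baseline-age interaction analyses should be run on an analysis set
assembled on the follow-up time scale (age cannot be both the time scale
and a covariate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cox import fit_by_country, fit_prentice_cox
from .meta import PooledEstimate, dl_random_effects

__all__ = [
    "InteractionResult",
    "fit_interaction",
    "stratified_hr",
    "outcome_by_age_at_diagnosis",
    "bonferroni_threshold",
    "SCORE_TEST_FAMILY",
]

# the default family of score-level interaction tests (m = 7)
SCORE_TEST_FAMILY = ("sex", "family_history", "bmi_group", "wc_group", "age", "pa_index", "diet_score")


class InestimableInteractionError(ValueError):
    pass


@dataclass
class InteractionResult:
    exposure: str
    factor: str
    beta: float
    se: float
    p: float
    tau2: float
    I2: float
    k: int
    per_country: pd.DataFrame
    threshold: float | None = None
    significant_after_bonferroni: bool | None = None

    def apply_threshold(self, threshold: float) -> "InteractionResult":
        self.threshold = float(threshold)
        self.significant_after_bonferroni = bool(self.p < threshold)
        return self


def _interaction_columns(df: pd.DataFrame, exposure: str, factor: str, coding: str) -> tuple[pd.DataFrame, list[str]]:
    out = df.copy()
    if coding in ("continuous", "ordinal"):
        # ordinal factors enter as equally spaced integers; one product term
        fac = out[factor].astype(float)
        term = f"{exposure}:{factor}"
        out["_factor"] = fac
        out[term] = out[exposure].astype(float) * fac
        return out, [term]
    if coding == "categorical":
        levels = sorted(pd.unique(df[factor].dropna()))
        terms = []
        for lev in levels[1:]:
            ind = (out[factor] == lev).astype(float)
            term = f"{exposure}:{factor}[{lev}]"
            out[term] = out[exposure].astype(float) * ind
            out[f"_factor[{lev}]"] = ind
            terms.append(term)
        return out, terms
    raise ValueError("coding must be 'continuous', 'ordinal' or 'categorical'")


def fit_interaction(
    data: pd.DataFrame,
    exposure: str,
    factor: str,
    coding: str = "ordinal",
    adjust: list[str] | None = None,
    min_events: int = 1,
    **kw,
) -> InteractionResult:
    """Pooled score-by-factor interaction across country-specific fits.

    The per-country model contains the exposure main effect, the factor main
    effect(s), the product term(s), and the adjustment covariates; countries
    with no events are dropped (k reduced).  The reported p-value is the
    Wald test on the pooled product-term coefficient.
    """
    if data[factor].nunique(dropna=True) < 2:
        raise InestimableInteractionError(f"factor {factor!r} is constant; interaction inestimable")
    adjust = list(adjust or [])
    df, terms = _interaction_columns(data, exposure, factor, coding)
    main_factor_cols = [c for c in df.columns if c.startswith("_factor")]
    covs = [exposure] + main_factor_cols + terms

    rows = []
    details = []
    for country, sub in df.groupby("country", observed=True, sort=True):
        if sub["event"].sum() < min_events or sub[factor].nunique(dropna=True) < 2:
            continue
        sub = sub.copy()
        adj = [a for a in adjust if sub[a].dtype.kind in "biufc" or sub[a].astype(str).nunique() > 1]
        for a in adj:
            if sub[a].dtype.kind not in "biufc":
                sub[a] = sub[a].astype(str)
        fit = fit_prentice_cox(sub, covs, adj, **kw)
        se = fit.se(robust=True)
        for term in terms:
            rows.append(
                {
                    "country": country,
                    "term": term,
                    "beta": float(fit.params[term]),
                    "se": float(se[term]),
                    "n_events": fit.n_events,
                }
            )
        details.append(fit)
    per_country = pd.DataFrame(rows)
    if per_country.empty or per_country["country"].nunique() < 2:
        raise InestimableInteractionError("fewer than two countries with estimable interaction")

    if len(terms) == 1:
        tab = per_country[per_country["term"] == terms[0]]
        pooled = dl_random_effects(tab["beta"], tab["se"])
        beta, se_, p = pooled.beta, pooled.se, pooled.p
        tau2, I2, k = pooled.tau2, pooled.I2, pooled.k
    else:
        # categorical coding: pool each product term, then a global Wald
        # statistic treating the pooled terms as independent
        chi2 = 0.0
        betas, ses_ = [], []
        tau2 = I2 = 0.0
        k = 0
        for term in terms:
            tab = per_country[per_country["term"] == term]
            pooled = dl_random_effects(tab["beta"], tab["se"])
            betas.append(pooled.beta)
            ses_.append(pooled.se)
            chi2 += (pooled.beta / pooled.se) ** 2
            tau2 = max(tau2, pooled.tau2)
            I2 = max(I2, pooled.I2)
            k = pooled.k
        beta = float(betas[np.argmax(np.abs(np.asarray(betas) / np.asarray(ses_)))])
        se_ = float(ses_[int(np.argmax(np.abs(np.asarray(betas) / np.asarray(ses_))))])
        p = float(stats.chi2.sf(chi2, df=len(terms)))
    return InteractionResult(
        exposure=exposure,
        factor=factor,
        beta=float(beta),
        se=float(se_),
        p=float(p),
        tau2=float(tau2),
        I2=float(I2),
        k=int(k),
        per_country=per_country,
    )


def stratified_hr(
    data: pd.DataFrame,
    exposure: str,
    factor: str,
    adjust: list[str] | None = None,
    sd_value: float | None = None,
    min_events: int = 1,
    **kw,
) -> pd.DataFrame:
    """Pooled exposure HR within each level of a risk factor.

    Separate per-country Prentice fits are run inside every factor level and
    pooled per level.  ``sd_value`` rescales estimates to the per-SD scale.
    Levels with no estimable fit are reported with missing values rather
    than dropped.  Passing ``adjust=[..., "bmi"]`` reproduces the
    obesity-adjusted sensitivity variant.
    """
    mult = float(sd_value) if sd_value else 1.0
    rows = []
    for level in sorted(pd.unique(data[factor].dropna())):
        sub = data[data[factor] == level]
        try:
            _, tab = fit_by_country(sub, [exposure], adjust, term=exposure, min_events=min_events, **kw)
            if len(tab) < 2:
                raise ValueError("fewer than two countries")
            pooled = dl_random_effects(tab["beta"], tab["se"])
            hr, lo, hi = pooled.hr_ci(mult)
            rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "n": len(sub),
                    "n_events": int(sub["event"].sum()),
                    "beta": pooled.beta * mult,
                    "se": pooled.se * mult,
                    "hr": hr,
                    "ci_low": lo,
                    "ci_high": hi,
                    "k": pooled.k,
                }
            )
        except (ValueError, KeyError):
            rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "n": len(sub),
                    "n_events": int(sub["event"].sum()),
                    "beta": np.nan,
                    "se": np.nan,
                    "hr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "k": 0,
                }
            )
    return pd.DataFrame(rows)


def outcome_by_age_at_diagnosis(
    data: pd.DataFrame,
    exposure: str,
    cut_ages: list[float] = (55.0, 65.0),
    adjust: list[str] | None = None,
    sd_value: float | None = None,
    **kw,
) -> pd.DataFrame:
    """Genetic effect with cases grouped by age at diagnosis.

    For each age-at-diagnosis group, cases diagnosed outside the group are
    censored at their event age (outside-the-sub-cohort cases so censored
    contribute to no Prentice risk set and drop out); each group is analysed
    as a separate outcome with per-country fits pooled across countries.
    Requires an age-scale analysis set (exit_age = age at diagnosis for
    cases).
    """
    cuts = list(cut_ages)
    if sorted(cuts) != cuts or len(set(cuts)) != len(cuts):
        raise ValueError("cut ages must be strictly increasing")
    edges = [-np.inf] + cuts + [np.inf]
    mult = float(sd_value) if sd_value else 1.0
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(lo):
            labels.append(f"<{hi:g}")
        elif np.isinf(hi):
            labels.append(f">={lo:g}")
        else:
            labels.append(f"{lo:g} to <{hi:g}")
    rows = []
    for (lo, hi), label in zip(zip(edges[:-1], edges[1:]), labels):
        sub = data.copy()
        case = sub["event"].astype(int) == 1
        in_group = case & (sub["exit_age"] >= lo) & (sub["exit_age"] < hi)
        sub.loc[case & ~in_group, "event"] = 0
        sub.loc[sub["event"] == 0, "role"] = np.where(
            sub.loc[sub["event"] == 0, "subcohort_flag"].astype(int) == 1,
            "subcohort_noncase",
            "outside_case",
        )
        sub = sub[(sub["event"] == 1) | (sub["subcohort_flag"].astype(int) == 1)]
        n_events = int(sub["event"].sum())
        if n_events == 0:
            rows.append({"group": label, "n_events": 0, "beta": np.nan, "se": np.nan, "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "inestimable": True})
            continue
        _, tab = fit_by_country(sub, [exposure], adjust, term=exposure, **kw)
        pooled = dl_random_effects(tab["beta"], tab["se"])
        hr, lo_ci, hi_ci = pooled.hr_ci(mult)
        rows.append(
            {
                "group": label,
                "n_events": n_events,
                "beta": pooled.beta * mult,
                "se": pooled.se * mult,
                "hr": hr,
                "ci_low": lo_ci,
                "ci_high": hi_ci,
                "inestimable": False,
            }
        )
    return pd.DataFrame(rows)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha/m controlling FWER at alpha."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive count")
    return alpha / m
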