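"""Prentice-weighted Cox regression for case-cohort data.

The estimation core of the package: a Newton–Raphson maximiser of the
case-cohort pseudo-partial-likelihood with left truncation (delayed entry),
per-row weights, Breslow or Efron tie handling, and a grouped sandwich
("robust") variance estimator built from score residuals.

Under the Prentice convention the risk set at each distinct failure time
consists of the sub-cohort members whose ``(entry, exit]`` interval covers
that time, plus the failing individual itself; a case outside the sub-cohort
enters the risk set only at its own failure time.  This is realised here by
moving the entry time of each outside case to just below its failure time
(half the minimum gap between distinct event times), after which the ordinary
left-truncated partial likelihood applies.  Self–Prentice (outside cases at
risk over their whole follow-up) and Barlow (inverse sampling-fraction
weights for sub-cohort non-cases) schemes are available for sensitivity
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxFitResult",
    "fit_cox",
    "fit_prentice_cox",
    "fit_by_country",
    "robust_variance",
    "hr_summary",
    "build_design_matrix",
]

_MAX_ITER = 50
_GTOL = 1e-6
_LTOL = 1e-9


class ConvergenceError(RuntimeError):
    pass


class SingularInformationError(np.linalg.LinAlgError):
    pass


@dataclass
class CoxFitResult:
    """Estimated log-hazard coefficients from one weighted Cox fit."""

    params: pd.Series
    naive_covariance: pd.DataFrame
    robust_covariance: pd.DataFrame
    log_pseudolikelihood: float
    iterations: int
    converged: bool
    n_events: int
    n_risk_rows: int
    ties: str = "breslow"
    scheme: str = "prentice"
    # internals needed to recompute residual-based variances
    _resid_groups: pd.DataFrame | None = field(default=None, repr=False)

    def se(self, robust: bool = True) -> pd.Series:
        cov = self.robust_covariance if robust else self.naive_covariance
        return pd.Series(np.sqrt(np.diag(cov.values)), index=self.params.index)

    def summary(self, robust: bool = True) -> pd.DataFrame:
        """Estimate table: term, beta, se, HR, 95% CI, Wald p."""
        se = self.se(robust=robust)
        z = self.params / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": se,
                "hr": np.exp(self.params),
                "ci_low": np.exp(self.params - 1.959963984540054 * se),
                "ci_high": np.exp(self.params + 1.959963984540054 * se),
                "p": p,
            }
        )


def build_design_matrix(data: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Expand a covariate list into a numeric design matrix.

    Numeric columns pass through unchanged; categorical/object columns are
    expanded into drop-first indicator columns (``col[level]``).  Raises on
    missing values so that complete-case subsetting is explicit upstream.
    """
    pieces = []
    for col in columns:
        if col not in data.columns:
            raise KeyError(f"covariate column {col!r} not found")
        s = data[col]
        if s.isna().any():
            raise ValueError(f"covariate {col!r} contains missing values; apply complete-case filtering first")
        if s.dtype.kind in "biufc":
            pieces.append(s.astype(float).rename(col))
        else:
            d = pd.get_dummies(s.astype("category"), prefix=col, prefix_sep="[", drop_first=True)
            d.columns = [c + "]" for c in d.columns]
            pieces.append(d.astype(float))
    X = pd.concat(pieces, axis=1)
    return X


def _prentice_entry(entry, exit_, event, role):
    """Shift outside-case entry times to just below their failure times."""
    entry = np.asarray(entry, float).copy()
    times = np.unique(np.asarray(exit_, float)[np.asarray(event, bool)])
    if times.size > 1:
        eps = 0.5 * np.min(np.diff(times))
    else:
        eps = 1e-6 * max(1.0, abs(float(times[0])) if times.size else 1.0)
    outside = np.asarray(role) == "outside_case"
    entry[outside] = np.asarray(exit_, float)[outside] - eps
    return entry


def _suffix_sums(order_vals, vals):
    """Suffix cumulative sums of `vals` in ascending order of `order_vals`."""
    o = np.argsort(order_vals, kind="stable")
    sorted_keys = order_vals[o]
    c = np.concatenate([np.cumsum(vals[o][::-1], axis=0)[::-1], np.zeros((1,) + vals.shape[1:])])
    return sorted_keys, c


def _loglik_breslow(beta, X, entry, exit_, event, w):
    r = w * np.exp(X @ beta)
    ev = event.astype(bool)
    t, inv = np.unique(exit_[ev], return_inverse=True)
    K = t.size
    p = X.shape[1]
    d = np.zeros(K)
    np.add.at(d, inv, w[ev])
    sx = np.zeros((K, p))
    np.add.at(sx, inv, (w[ev, None] * X[ev]))

    rx = r[:, None] * X
    rxx = rx[:, :, None] * X[:, None, :]
    ek, c0e = _suffix_sums(exit_, r)
    _, c1e = _suffix_sums(exit_, rx)
    _, c2e = _suffix_sums(exit_, rxx)
    nk, c0n = _suffix_sums(entry, r)
    _, c1n = _suffix_sums(entry, rx)
    _, c2n = _suffix_sums(entry, rxx)

    ie = np.searchsorted(ek, t, side="left")
    inn = np.searchsorted(nk, t, side="left")
    S0 = c0e[ie] - c0n[inn]
    S1 = c1e[ie] - c1n[inn]
    S2 = c2e[ie] - c2n[inn]
    if np.any(S0 <= 0):
        raise FloatingPointError("empty risk set at an event time")

    xbar = S1 / S0[:, None]
    ll = float(np.sum(w[ev] * (X[ev] @ beta)) - np.sum(d * np.log(S0)))
    grad = sx.sum(axis=0) - (d[:, None] * xbar).sum(axis=0)
    hess = -(
        np.einsum("k,kij->ij", d / S0, S2)
        - np.einsum("k,ki,kj->ij", d, xbar, xbar)
    )
    return ll, grad, hess, (t, d, S0, S1, xbar)


def _loglik_efron(beta, X, entry, exit_, event, w):
    # loop over tie groups; fine for the moderate event counts used here
    r = w * np.exp(X @ beta)
    ev = event.astype(bool)
    t = np.unique(exit_[ev])
    p = X.shape[1]
    ll = float(np.sum(w[ev] * (X[ev] @ beta)))
    grad = (w[ev, None] * X[ev]).sum(axis=0)
    hess = np.zeros((p, p))
    rx = r[:, None] * X
    rxx = rx[:, :, None] * X[:, None, :]
    for tk in t:
        at_risk = (entry < tk) & (exit_ >= tk)
        tied = ev & (exit_ == tk)
        m = int(tied.sum())
        wk = w[tied].sum() / m
        S0 = r[at_risk].sum()
        S1 = rx[at_risk].sum(axis=0)
        S2 = rxx[at_risk].sum(axis=0)
        S0e = r[tied].sum()
        S1e = rx[tied].sum(axis=0)
        S2e = rxx[tied].sum(axis=0)
        for j in range(m):
            f = j / m
            D0 = S0 - f * S0e
            D1 = S1 - f * S1e
            D2 = S2 - f * S2e
            ll -= wk * np.log(D0)
            xb = D1 / D0
            grad -= wk * xb
            hess -= wk * (D2 / D0 - np.outer(xb, xb))
    return ll, grad, hess, None


def _newton(X, entry, exit_, event, w, ties):
    loglik = _loglik_breslow if ties == "breslow" else _loglik_efron
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess, aux = loglik(beta, X, entry, exit_, event, w)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            _raise_singular(-hess, X)
        # step halving: insist the pseudo-likelihood does not decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            try:
                ll_new, grad_new, hess_new, aux_new = loglik(cand, X, entry, exit_, event, w)
            except FloatingPointError:
                ll_new = -np.inf
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        else:
            break
        beta, delta = cand, ll_new - ll
        ll, grad, hess, aux = ll_new, grad_new, hess_new, aux_new
        if np.max(np.abs(grad)) < _GTOL and abs(delta) < _LTOL * (abs(ll) + 1.0):
            converged = True
            break
    return beta, ll, grad, hess, aux, it, converged


def _raise_singular(info, X):
    # name near-collinear columns by inspecting the null space
    u, s, vt = np.linalg.svd(info)
    bad = vt[np.abs(s) < 1e-10 * max(s.max(), 1.0)]
    cols = []
    for v in bad:
        cols.extend(np.where(np.abs(v) > 1e-3)[0].tolist())
    raise SingularInformationError(
        f"singular information matrix; collinear columns: {sorted(set(cols))}"
    )


def _score_residuals(beta, X, entry, exit_, event, w, aux):
    """Breslow score residuals per row (used for the sandwich variance)."""
    t, d, S0, S1, xbar = aux
    r = w * np.exp(X @ beta)
    ev = event.astype(bool)
    U = np.zeros_like(X)
    # event part
    idx = np.searchsorted(t, exit_[ev])
    U[ev] = w[ev, None] * (X[ev] - xbar[idx])
    # cumulative-hazard part over event times in (entry_i, exit_i]
    A = np.concatenate([[0.0], np.cumsum(d / S0)])
    B = np.concatenate([np.zeros((1, X.shape[1])), np.cumsum(d[:, None] * S1 / S0[:, None] ** 2, axis=0)])
    hi = np.searchsorted(t, exit_, side="right")
    lo = np.searchsorted(t, entry, side="right")
    U -= r[:, None] * (X * (A[hi] - A[lo])[:, None] - (B[hi] - B[lo]))
    return U


def fit_cox(
    data: pd.DataFrame,
    covariates: list[str],
    *,
    entry_col: str = "entry_time",
    exit_col: str = "exit_time",
    event_col: str = "event",
    weight_col: str | None = None,
    id_col: str = "participant_id",
    ties: str = "breslow",
    strata: str | None = None,
) -> CoxFitResult:
    """Weighted Cox regression with left truncation (no case-cohort reweighting).

    ``strata`` fits separate baseline hazards per stratum by summing the
    stratum-wise pseudo-likelihood contributions.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    Xdf = build_design_matrix(data, covariates)
    terms = list(Xdf.columns)
    X = Xdf.values.astype(float)
    entry = data[entry_col].to_numpy(float)
    exit_ = data[exit_col].to_numpy(float)
    event = data[event_col].to_numpy(float)
    if np.any(exit_ <= entry):
        bad = data.index[exit_ <= entry][:5].tolist()
        raise ValueError(f"exit_time <= entry_time for rows {bad}")
    if event.sum() < 1:
        raise ValueError("no events in data")
    w = data[weight_col].to_numpy(float) if weight_col else np.ones(len(data))

    # constant columns carry no information: fix their coefficient at zero
    keep = X.std(axis=0) > 0
    Xfit = X[:, keep]
    p_all = X.shape[1]

    if strata is None:
        groups = [np.arange(len(data))]
    else:
        groups = [np.where(data[strata].to_numpy() == g)[0] for g in pd.unique(data[strata])]

    if Xfit.shape[1] == 0:
        beta_fit = np.zeros(0)
        ll = 0.0
        hess = np.zeros((0, 0))
        it, converged = 0, True
        Uall = np.zeros((len(data), 0))
    elif strata is None and ties == "breslow":
        beta_fit, ll, grad, hess, aux, it, converged = _newton(Xfit, entry, exit_, event, w, ties)
        Uall = _score_residuals(beta_fit, Xfit, entry, exit_, event, w, aux)
    else:
        beta_fit, ll, hess, it, converged, Uall = _newton_stratified(
            Xfit, entry, exit_, event, w, ties, groups
        )

    beta = np.zeros(p_all)
    beta[keep] = beta_fit
    info = np.zeros((p_all, p_all))
    naive = np.zeros((p_all, p_all))
    if Xfit.shape[1] > 0:
        try:
            naive_fit = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            _raise_singular(-hess, Xfit)
        naive[np.ix_(keep, keep)] = naive_fit
    U = np.zeros((len(data), p_all))
    U[:, keep] = Uall

    # grouped sandwich: sum score residuals within participant
    resid = pd.DataFrame(U, index=pd.Index(data[id_col].to_numpy(), name=id_col))
    Ug = resid.groupby(level=0).sum().values
    robust = naive @ (Ug.T @ Ug) @ naive if p_all else naive

    return CoxFitResult(
        params=pd.Series(beta, index=terms),
        naive_covariance=pd.DataFrame(naive, index=terms, columns=terms),
        robust_covariance=pd.DataFrame(robust, index=terms, columns=terms),
        log_pseudolikelihood=float(ll),
        iterations=it,
        converged=bool(converged),
        n_events=int(event.sum()),
        n_risk_rows=int(len(data)),
        ties=ties,
        _resid_groups=pd.DataFrame(Ug),
    )


def _newton_stratified(X, entry, exit_, event, w, ties, groups):
    """Newton solver summing pseudo-likelihood pieces over baseline strata."""
    loglik = _loglik_breslow if ties == "breslow" else _loglik_efron
    p = X.shape[1]

    def total(beta):
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        auxes = []
        for g in groups:
            if event[g].sum() == 0:
                auxes.append(None)
                continue
            l, gr, h, aux = loglik(beta, X[g], entry[g], exit_[g], event[g], w[g])
            ll += l
            grad += gr
            hess += h
            auxes.append(aux)
        return ll, grad, hess, auxes

    beta = np.zeros(p)
    ll, grad, hess, auxes = total(beta)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            _raise_singular(-hess, X)
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            try:
                ll_new, grad_new, hess_new, aux_new = total(cand)
            except FloatingPointError:
                ll_new = -np.inf
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        else:
            break
        beta, delta = cand, ll_new - ll
        ll, grad, hess, auxes = ll_new, grad_new, hess_new, aux_new
        if np.max(np.abs(grad)) < _GTOL and abs(delta) < _LTOL * (abs(ll) + 1.0):
            converged = True
            break

    U = np.zeros((X.shape[0], p))
    if ties == "breslow":
        for g, aux in zip(groups, auxes):
            if aux is None:
                continue
            U[g] = _score_residuals(beta, X[g], entry[g], exit_[g], event[g], w[g], aux)
    else:
        # Efron residuals approximated by Breslow-form residuals at beta-hat
        for g in groups:
            if event[g].sum() == 0:
                continue
            _, _, _, aux = _loglik_breslow(beta, X[g], entry[g], exit_[g], event[g], w[g])
            U[g] = _score_residuals(beta, X[g], entry[g], exit_[g], event[g], w[g], aux)
    return beta, ll, hess, it, converged, U


def fit_prentice_cox(
    data: pd.DataFrame,
    covariates: list[str],
    adjust: list[str] | None = None,
    *,
    scheme: str = "prentice",
    subcohort_fraction: float | None = None,
    ties: str = "breslow",
    strata: str | None = None,
    **kw,
) -> CoxFitResult:
    """Fit the case-cohort pseudo-partial-likelihood on an analysis set.

    Parameters
    ----------
    data
        Analysis set with ``role`` in {subcohort_noncase, subcohort_case,
        outside_case}, ``entry_time``/``exit_time``/``event`` columns, and the
        model covariates.
    covariates, adjust
        Exposure terms of interest and adjustment terms; both enter the
        linear predictor identically (the split is bookkeeping for callers).
    scheme
        'prentice' (default), 'self-prentice', or 'barlow'
        (requires ``subcohort_fraction``).
    """
    adjust = adjust or []
    cols = list(covariates) + [a for a in adjust if a not in covariates]
    df = data.copy()
    if "role" not in df.columns:
        raise KeyError("analysis set must carry a 'role' column")
    entry = df["entry_time"].to_numpy(float)
    exit_ = df["exit_time"].to_numpy(float)
    event = df["event"].to_numpy(float)
    role = df["role"].to_numpy()

    if scheme == "prentice":
        df["entry_time"] = _prentice_entry(entry, exit_, event, role)
        weight_col = None
    elif scheme == "self-prentice":
        weight_col = None
    elif scheme == "barlow":
        if not subcohort_fraction or not (0 < subcohort_fraction <= 1):
            raise ValueError("barlow scheme requires subcohort_fraction in (0,1]")
        w = np.ones(len(df))
        w[(role != "outside_case") & (event == 0)] = 1.0 / subcohort_fraction
        df["_w"] = w
        weight_col = "_w"
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    res = fit_cox(df, cols, weight_col=weight_col, ties=ties, strata=strata, **kw)
    res.scheme = scheme
    return res


def robust_variance(fit: CoxFitResult) -> pd.DataFrame:
    """Grouped sandwich covariance of a converged fit.

    Sandwich of the per-participant summed score residuals around the
    inverse information; equals the robust Cox variance when the sub-cohort
    is the whole cohort.
    """
    if not fit.converged:
        raise ConvergenceError("robust variance requires a converged fit")
    return fit.robust_covariance


def hr_summary(
    fit: CoxFitResult,
    term: str,
    scale: str = "per_allele",
    sd_value: float | None = None,
    robust: bool = True,
) -> tuple[float, float, float]:
    """Hazard ratio with 95% CI for one term, per allele or per reference SD."""
    if term not in fit.params.index:
        raise KeyError(f"term {term!r} not in fit")
    mult = 1.0
    if scale == "per_sd":
        if sd_value is None or sd_value <= 0:
            raise ValueError("per_sd scale requires sd_value > 0")
        mult = float(sd_value)
    elif scale != "per_allele":
        raise ValueError("scale must be 'per_allele' or 'per_sd'")
    b = fit.params[term] * mult
    s = fit.se(robust=robust)[term] * mult
    return float(np.exp(b)), float(np.exp(b - 1.959963984540054 * s)), float(np.exp(b + 1.959963984540054 * s))


def fit_by_country(
    data: pd.DataFrame,
    covariates: list[str],
    adjust: list[str] | None = None,
    term: str | None = None,
    min_events: int = 1,
    **kw,
) -> tuple[dict, pd.DataFrame]:
    """Country-specific Prentice fits plus a per-country estimate table.

    Countries with fewer than ``min_events`` events are dropped with a
    recorded note.  When ``term`` is given, returns a table of (country,
    beta, se, n_events) for that term, ready for random-effects pooling.
    Within-country centre adjustment drops centre indicator levels absent
    from that country automatically (categoricals are re-coded per country).
    """
    fits = {}
    rows = []
    for country, sub in data.groupby("country", observed=True, sort=True):
        if sub["event"].sum() < min_events:
            continue
        sub = sub.copy()
        for c in (adjust or []):
            if sub[c].dtype.kind not in "biufc":
                sub[c] = sub[c].astype(str)
        # centre indicators are only meaningful if >1 centre in the country
        adj = [
            a
            for a in (adjust or [])
            if sub[a].nunique() > 1 or sub[a].dtype.kind in "biufc"
        ]
        fit = fit_prentice_cox(sub, covariates, adj, **kw)
        fits[country] = fit
        if term is not None:
            rows.append(
                {
                    "country": country,
                    "beta": float(fit.params[term]),
                    "se": float(fit.se(robust=True)[term]),
                    "n_events": fit.n_events,
                }
            )
    table = pd.DataFrame(rows) if term is not None else pd.DataFrame()
    return fits, table
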