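"""Random-effects pooling of per-country estimates and meta-regression.

DerSimonian–Laird method-of-moments estimation: fixed-effect weights
``w_i = 1/se_i^2`` give Cochran's Q; the between-country variance is
``tau2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))``; the pooled
estimate re-weights by ``1/(se_i^2 + tau2)``.  ``I2 = max(0, (Q-(k-1))/Q)``
is the share of total variability attributable to heterogeneity.
Meta-regression fits country-level moderators by weighted least squares with
a method-of-moments residual tau2; with an intercept only it reduces
exactly to the random-effects pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PooledEstimate", "dl_random_effects", "meta_regression", "forest_table"]


@dataclass
class PooledEstimate:
    beta: float
    se: float
    tau2: float
    Q: float
    I2: float
    k: int
    weights: np.ndarray

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.beta / self.se)))

    def hr_ci(self, mult: float = 1.0) -> tuple[float, float, float]:
        b, s = self.beta * mult, self.se * mult
        return (
            float(np.exp(b)),
            float(np.exp(b - 1.959963984540054 * s)),
            float(np.exp(b + 1.959963984540054 * s)),
        )


def _check(betas, ses):
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if betas.shape != ses.shape or betas.ndim != 1:
        raise ValueError("betas and ses must be 1-D and of equal length")
    if len(betas) < 2:
        raise ValueError("pooling requires at least two estimates")
    if np.any(~np.isfinite(betas)):
        raise ValueError("non-finite estimate")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    return betas, ses


def dl_random_effects(betas, ses) -> PooledEstimate:
    """DerSimonian–Laird random-effects pool of k independent estimates."""
    betas, ses = _check(betas, ses)
    w = 1.0 / ses**2
    beta_fe = float(np.sum(w * betas) / np.sum(w))
    Q = float(np.sum(w * (betas - beta_fe) ** 2))
    k = len(betas)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    wstar = 1.0 / (ses**2 + tau2)
    beta_re = float(np.sum(wstar * betas) / np.sum(wstar))
    se_re = float(np.sqrt(1.0 / np.sum(wstar)))
    I2 = max(0.0, (Q - (k - 1)) / Q) if Q > 0 else 0.0
    return PooledEstimate(beta=beta_re, se=se_re, tau2=float(tau2), Q=Q, I2=float(I2), k=k, weights=wstar)


@dataclass
class MetaRegressionResult:
    coef: pd.Series
    se: pd.Series
    residual_tau2: float
    k: int

    @property
    def p(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.coef / self.se)), index=self.coef.index)


def meta_regression(betas, ses, moderators: pd.DataFrame) -> MetaRegressionResult:
    """Weighted regression of estimates on country-level moderators.

    Moderators are country-level means (e.g. average age, BMI or waist
    circumference in the sub-cohort).  Residual between-country variance is
    the method-of-moments estimate
    ``tau2 = max(0, (QE - (k - p)) / (tr(W) - tr((X'WX)^-1 X'W^2 X)))``
    from the fixed-effect (w=1/se^2) residual QE, after which coefficients
    are re-estimated with weights ``1/(se^2 + tau2)``.
    """
    betas, ses = _check(betas, ses)
    X = pd.DataFrame(moderators).copy()
    X.insert(0, "intercept", 1.0)
    if len(X) != len(betas):
        raise ValueError("moderator rows must match number of estimates")
    k, p = X.shape
    if k <= p:
        raise ValueError("need more countries than moderators + intercept")
    Xv = X.to_numpy(float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        # identify a minimal set of dependent columns by greedy QR
        _, R = np.linalg.qr(Xv)
        dep = [X.columns[i] for i in range(p) if abs(R[i, i]) < 1e-10]
        raise ValueError(f"collinear moderators: {dep}")

    w = 1.0 / ses**2
    W = np.diag(w)
    XtWX = Xv.T @ W @ Xv
    b_fe = np.linalg.solve(XtWX, Xv.T @ (w * betas))
    resid = betas - Xv @ b_fe
    QE = float(np.sum(w * resid**2))
    trace = np.trace(W) - np.trace(np.linalg.solve(XtWX, Xv.T @ np.diag(w**2) @ Xv))
    tau2 = max(0.0, (QE - (k - p)) / trace) if trace > 0 else 0.0

    wstar = 1.0 / (ses**2 + tau2)
    Ws = np.diag(wstar)
    XtWsX = Xv.T @ Ws @ Xv
    b = np.linalg.solve(XtWsX, Xv.T @ (wstar * betas))
    cov = np.linalg.inv(XtWsX)
    return MetaRegressionResult(
        coef=pd.Series(b, index=X.columns),
        se=pd.Series(np.sqrt(np.diag(cov)), index=X.columns),
        residual_tau2=float(tau2),
        k=k,
    )


def forest_table(country_table: pd.DataFrame, pooled: PooledEstimate, mult: float = 1.0) -> pd.DataFrame:
    """Per-country and pooled rows (country, beta, se, HR, CI, weight) for a
    forest-style summary."""
    z = 1.959963984540054
    rows = []
    for _, r in country_table.iterrows():
        b, s = r["beta"] * mult, r["se"] * mult
        rows.append(
            {
                "country": r["country"],
                "beta": b,
                "se": s,
                "hr": np.exp(b),
                "ci_low": np.exp(b - z * s),
                "ci_high": np.exp(b + z * s),
                "weight_pct": np.nan,
                "n_events": r.get("n_events", np.nan),
            }
        )
    wsum = pooled.weights.sum()
    for row, w in zip(rows, pooled.weights):
        row["weight_pct"] = 100.0 * w / wsum
    b, s = pooled.beta * mult, pooled.se * mult
    rows.append(
        {
            "country": "overall",
            "beta": b,
            "se": s,
            "hr": np.exp(b),
            "ci_low": np.exp(b - z * s),
            "ci_high": np.exp(b + z * s),
            "weight_pct": 100.0,
            "n_events": country_table.get("n_events", pd.Series(dtype=float)).sum(),
        }
    )
    return pd.DataFrame(rows)
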