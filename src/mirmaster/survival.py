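"""Survival analysis: Kaplan-Meier, log-rank, mean-expression stratification
and Cox proportional hazards (Breslow ties, Newton-Raphson).

The log-rank test reports per-group observed and expected event counts
alongside the chi-square statistic; the Cox fitter maximizes the Breslow
partial likelihood with step-halving and flags monotone-likelihood
divergence instead of reporting runaway hazard ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .io import ValidationError

logger = logging.getLogger("mirmaster")


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier curve for one group; all-censored input warns and stays flat."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValidationError("empty survival data")
    if (time < 0).any():
        raise ValidationError("negative survival times")
    if event.sum() == 0:
        logger.warning("all-censored group: Kaplan-Meier curve is flat at 1")
        return KMCurve(np.array([]), np.array([]), np.array([]), np.sort(time))
    kmf = KaplanMeierFitter().fit(time, event)
    table = kmf.event_table
    has_event = table["observed"] > 0
    ts = table.index.to_numpy(dtype=float)[has_event]
    surv = kmf.survival_function_at_times(ts).to_numpy()
    at_risk = table.loc[has_event, "at_risk"].to_numpy()
    return KMCurve(ts, surv, at_risk, np.sort(time[event == 0]))


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p: float
    observed: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)


def logrank_test(time, event, group) -> LogRankResult:
    """Two-group log-rank test with per-group O and E.

    At each distinct event time the group-1 expected count and hypergeometric
    variance accumulate; chi2 = (O1 - E1)^2 / V with 1 df.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist())
    if len(levels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {levels}")
    g1 = group == levels[0]
    if g1.all() or not g1.any():
        raise ValidationError("one log-rank group is empty")
    o1 = e1 = v = 0.0
    obs = {lv: float(event[group == lv].sum()) for lv in levels}
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = int(event[at_risk & (time == t)].sum())
        d1 = int(event[at_risk & (time == t) & g1].sum())
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (o1 - e1) ** 2 / v if v > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if v > 0 else 1.0
    exp = {levels[0]: e1, levels[1]: sum(obs.values()) - e1}
    return LogRankResult(chi_square=float(chi2), df=1, p=p, observed=obs, expected=exp)


def stratify_by_mean(values, sample_ids=None) -> pd.Series:
    """Split samples at the cohort mean: strictly above -> "high", else "low"."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("stratification needs >= 2 samples")
    if np.ptp(values) == 0:
        logger.warning("constant expression vector: all samples stratified low")
    labels = np.where(values > values.mean(), "high", "low")
    index = sample_ids if sample_ids is not None else np.arange(values.size)
    return pd.Series(labels, index=index, name="stratum")


@dataclass
class CoxFit:
    covariates: list[str]
    coef: np.ndarray
    hazard_ratio: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    converged: bool
    log_likelihood: float
    n_iter: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.covariates,
            "coef": self.coef,
            "HR": self.hazard_ratio,
            "se": self.se,
            "HR_ci_lower": self.ci_lower,
            "HR_ci_upper": self.ci_upper,
        })


def _breslow_loglik(beta, time, event, X):
    """Breslow log partial likelihood plus gradient and information matrix."""
    order = np.argsort(-time, kind="stable")
    t, e, Xs = time[order], event[order], X[order]
    eta = Xs @ beta
    w = np.exp(eta)
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w[:, None] * Xs, axis=0)
    cum_wxx = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    ll, grad, info = 0.0, np.zeros(X.shape[1]), np.zeros((X.shape[1], X.shape[1]))
    i = 0
    n = t.size
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # risk set for time t[i] spans positions 0..j-1 (times >= t[i])
        W, WX, WXX = cum_w[j - 1], cum_wx[j - 1], cum_wxx[j - 1]
        ev = slice(i, j)
        d = int(e[ev].sum())
        if d > 0:
            xb = Xs[ev][e[ev] == 1]
            ll += (xb @ beta).sum() - d * np.log(W)
            mu = WX / W
            grad += xb.sum(axis=0) - d * mu
            info += d * (WXX / W - np.outer(mu, mu))
        i = j
    return ll, grad, info


def cox_fit(time, event, covariates: pd.DataFrame, max_iter: int = 50,
            tol: float = 1e-8) -> CoxFit:
    """Cox proportional-hazards fit (Breslow ties) by safeguarded Newton-Raphson.

    Convergence on the score norm; each Newton step is halved until the log
    partial likelihood does not decrease. |beta| escaping 10 flags monotone
    likelihood and the fit is reported unconverged without hazard ratios.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = covariates.to_numpy(dtype=float)
    if event.sum() == 0:
        raise ValidationError("Cox fit requires at least one event")
    if not np.isfinite(X).all():
        raise ValidationError("covariates must be finite")
    constant = [c for c, s in zip(covariates.columns, X.std(axis=0)) if s == 0]
    if constant:
        raise ValidationError(f"constant covariates: {constant}")
    X = X - X.mean(axis=0)  # centering improves conditioning; beta unchanged

    beta = np.zeros(X.shape[1])
    ll, grad, info = _breslow_loglik(beta, time, event, X)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):  # step-halving: never let the likelihood decrease
            cand = beta + scale * step
            ll_new, grad_new, info_new = _breslow_loglik(cand, time, event, X)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.abs(beta).max() > 10:
            logger.warning("Cox fit: coefficient escaping (monotone likelihood); "
                           "fit flagged unconverged")
            return CoxFit(list(covariates.columns), beta, np.full_like(beta, np.nan),
                          np.full_like(beta, np.nan), np.full_like(beta, np.nan),
                          np.full_like(beta, np.nan), False, ll, it)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
    if not converged:
        logger.warning("Cox fit did not converge in %d iterations", max_iter)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    hr = np.exp(beta)
    return CoxFit(
        covariates=list(covariates.columns),
        coef=beta,
        hazard_ratio=hr,
        se=se,
        ci_lower=np.exp(beta - 1.959963984540054 * se),
        ci_upper=np.exp(beta + 1.959963984540054 * se),
        converged=converged,
        log_likelihood=float(ll),
        n_iter=it,
    )
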