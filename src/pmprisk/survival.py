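"""Survival and classifier-evaluation statistics.

Self-contained implementations of the evaluation toolbox used by the
risk-classification pipeline:

* horizon binarization of disease-free survival (event within H months
  vs event-free at H months; units censored before the horizon are
  indeterminate and excluded from ROC analysis),
* empirical ROC curves with trapezoidal AUC (ties receive the usual
  half credit, so the AUC equals the Mann-Whitney concordance),
* DeLong variance/covariance of correlated AUCs via placement values,
  with the paired z-test and normal-approximation confidence intervals,
* the Kaplan-Meier product-limit estimator,
* the log-rank test (2 groups via the classic (O-E)^2/V form; k groups
  via the hypergeometric covariance matrix),
* Cox proportional hazards with Breslow tie handling (Newton-Raphson on
  the partial likelihood), and
* the two-sample t-test (Welch default, pooled optional).

Only distribution functions (chi-square, normal, Student t) come from
scipy; the statistics themselves are computed here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import ValidationError
from .multilesion import CohortAnnotation

logger = logging.getLogger("pmprisk")

EVENT_WITHIN = "event_within_horizon"
EVENT_FREE = "event_free_at_horizon"
INDETERMINATE = "indeterminate"


# ---------------------------------------------------------------------------
# Horizon binarization
# ---------------------------------------------------------------------------

@dataclass
class BinaryOutcomeTable:
    """Per-unit binary outcome at a fixed follow-up horizon."""

    outcome: pd.Series  # values in {EVENT_WITHIN, EVENT_FREE, INDETERMINATE}
    horizon_months: float

    def positives_negatives(self) -> tuple[pd.Index, pd.Index]:
        pos = self.outcome.index[self.outcome == EVENT_WITHIN]
        neg = self.outcome.index[self.outcome == EVENT_FREE]
        return pos, neg


def binarize_dfs(ann: CohortAnnotation, horizon_months: float = 24.0,
                 unit: str = "sample") -> BinaryOutcomeTable:
    """Binarize DFS at a horizon (default 24 months).

    An event at or before the horizon is ``event_within_horizon``; units
    followed (with or without a later event) to at least the horizon are
    ``event_free_at_horizon``; units censored before the horizon are
    ``indeterminate``.  ``unit`` selects sample-level (each lesion carries
    its patient's outcome) or patient-level rows.
    """
    if horizon_months <= 0:
        raise ValidationError("horizon must be positive")
    if unit == "sample":
        t = ann.table["dfs_months"]
        e = ann.table["dfs_event"]
    elif unit == "patient":
        pt = ann.patient_table()
        t = pt["dfs_months"]
        e = pt["dfs_event"]
    else:
        raise ValidationError(f"unknown unit {unit!r}")
    if (t.to_numpy() < 0).any():
        raise ValidationError("negative survival times")
    out = np.where(e & (t <= horizon_months), EVENT_WITHIN,
                   np.where(t >= horizon_months, EVENT_FREE, INDETERMINATE))
    return BinaryOutcomeTable(outcome=pd.Series(out, index=t.index),
                              horizon_months=float(horizon_months))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    n_indeterminate: int = 0


def _align_scores_outcomes(scores: pd.Series, outcomes: BinaryOutcomeTable,
                           ) -> tuple[np.ndarray, np.ndarray, int]:
    units = outcomes.outcome.index
    missing = [u for u in units if u not in scores.index]
    if missing:
        raise ValidationError(f"units without scores: {missing[:10]}")
    keep = outcomes.outcome != INDETERMINATE
    n_ind = int((~keep).sum())
    if n_ind:
        logger.info("ROC: excluding %d units censored before the %g-month horizon",
                    n_ind, outcomes.horizon_months)
    kept = outcomes.outcome[keep]
    s = scores.loc[kept.index].to_numpy(dtype=float)
    y = (kept == EVENT_WITHIN).to_numpy()
    return s, y, n_ind


def roc_auc(scores: pd.Series, outcomes: BinaryOutcomeTable) -> ROCResult:
    """Empirical ROC curve and trapezoidal AUC (ties get half credit)."""
    s, y, n_ind = _align_scores_outcomes(scores, outcomes)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs at least one positive and one negative unit")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # indices where the threshold changes (group tied scores together)
    distinct = np.where(np.diff(s_sorted))[0]
    boundaries = np.concatenate([distinct, [len(s_sorted) - 1]])
    tps = np.cumsum(y_sorted)[boundaries]
    fps = (boundaries + 1) - tps
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc, n_pos=n_pos, n_neg=n_neg,
                     n_indeterminate=n_ind)


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0  # average of 1-based ranks i+1..j
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def _delong_components(s: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and placement values (structural components) for one score vector."""
    pos = s[y]
    neg = s[~y]
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n            # one value per positive
    v01 = 1.0 - (tz[m:] - ty) / m      # one value per negative
    return float(auc), v10, v01


def delong_ci(scores: pd.Series, outcomes: BinaryOutcomeTable,
              level: float = 0.95) -> dict:
    """DeLong variance-based normal CI for one AUC, truncated to [0, 1]."""
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    s, y, _ = _align_scores_outcomes(scores, outcomes)
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise ValidationError("DeLong CI needs both outcome classes")
    auc, v10, v01 = _delong_components(s, y)
    flagged = m < 2 or n < 2
    var = 0.0 if flagged else float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(_st.norm.ppf(0.5 + level / 2.0))
    lower = max(0.0, auc - z * se)
    upper = min(1.0, auc + z * se)
    return {"auc": auc, "se": se, "lower": lower, "upper": upper,
            "level": level, "flagged": flagged}


def delong_compare(scores_a: pd.Series, scores_b: pd.Series,
                   outcomes: BinaryOutcomeTable) -> dict:
    """DeLong paired comparison of two correlated AUCs on identical units.

    Returns auc_a, auc_b, z, p_value; degenerate variance (e.g. identical
    scores) yields z = 0, p = 1 when the AUCs agree and a flagged result
    otherwise.
    """
    if set(scores_a.index) != set(scores_b.index):
        raise ValidationError("delong_compare: score vectors must cover identical units")
    sa, y, _ = _align_scores_outcomes(scores_a, outcomes)
    sb, _, _ = _align_scores_outcomes(scores_b.loc[scores_a.index], outcomes)
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise ValidationError("DeLong comparison needs both outcome classes")
    auc_a, v10a, v01a = _delong_components(sa, y)
    auc_b, v10b, v01b = _delong_components(sb, y)
    flagged = False
    if m < 2 or n < 2:
        var_diff = 0.0
    else:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var_diff = float((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
                         + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    diff = auc_a - auc_b
    if var_diff <= 1e-15:
        if abs(diff) <= 1e-12:
            z_stat, p = 0.0, 1.0
        else:
            z_stat, p = float("nan"), float("nan")
            flagged = True
            logger.warning("delong_compare: degenerate variance with unequal AUCs")
    else:
        z_stat = diff / float(np.sqrt(var_diff))
        p = float(2.0 * _st.norm.sf(abs(z_stat)))
    return {"auc_a": auc_a, "auc_b": auc_b, "z": z_stat, "p_value": p,
            "var_diff": var_diff, "flagged": flagged}


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """Product-limit estimate on the grid of distinct observed times.

    ``times`` starts at 0 with S(0) = 1; ``at_risk`` and ``n_events``
    describe the risk set just before / events at each grid time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_fit(times: Sequence[float], events: Sequence[bool],
           groups: Optional[Sequence] = None):
    """Kaplan-Meier product-limit estimator.

    Without ``groups`` returns a single :class:`SurvivalFit`; with group
    labels returns a dict label → fit (empty groups are an error).
    Censored units leave the risk set after their censoring time.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValidationError("times and events must be 1-D and equally long")
    if (t < 0).any():
        raise ValidationError("negative survival times")
    if groups is None:
        return _km_single(t, e)
    g = np.asarray(groups)
    out: Dict[object, SurvivalFit] = {}
    for label in pd.unique(g):
        mask = g == label
        if not mask.any():
            raise ValidationError(f"empty group {label!r}")
        out[label] = _km_single(t[mask], e[mask])
    return out


def _km_single(t: np.ndarray, e: np.ndarray) -> SurvivalFit:
    if len(t) == 0:
        raise ValidationError("empty group in Kaplan-Meier fit")
    grid = np.unique(t)
    times = [0.0]
    surv = [1.0]
    at_risk = [len(t)]
    n_events = [0]
    s = 1.0
    n_risk = len(t)
    for tt in grid:
        d = int((e & (t == tt)).sum())
        c = int((~e & (t == tt)).sum())
        if d > 0:
            s *= 1.0 - d / n_risk
        times.append(float(tt))
        surv.append(s)
        at_risk.append(n_risk)
        n_events.append(d)
        n_risk -= d + c
    return SurvivalFit(times=np.array(times), survival=np.array(surv),
                       at_risk=np.array(at_risk), n_events=np.array(n_events))


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    df: int
    observed: dict
    expected: dict
    flagged: bool = False


def logrank_test(times: Sequence[float], events: Sequence[bool],
                 groups: Sequence) -> LogRankResult:
    """Log-rank test across 2 (or more) groups.

    Per distinct event time the observed events per group are compared
    with the hypergeometric expectation given the risk sets; for two
    groups the statistic is (ΣO−ΣE)²/ΣV on 1 df, for k groups the
    quadratic form with the covariance matrix on k−1 df.  With no events
    at all the statistic is 0, p = 1, flagged.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    if not (len(t) == len(e) == len(g)):
        raise ValidationError("times, events and groups must be equally long")
    labels = pd.unique(g).tolist()
    k = len(labels)
    if k < 2:
        raise ValidationError("log-rank test needs at least two groups")
    for label in labels:
        if not (g == label).any():
            raise ValidationError(f"empty group {label!r}")

    event_times = np.unique(t[e])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for tt in event_times:
        at_risk = t >= tt
        n = int(at_risk.sum())
        d = int((e & (t == tt)).sum())
        n_g = np.array([(at_risk & (g == label)).sum() for label in labels], dtype=float)
        o_g = np.array([((t == tt) & e & (g == label)).sum() for label in labels], dtype=float)
        observed += o_g
        expected += d * n_g / n
        if n > 1:
            frac = n_g / n
            hyper = d * (n - d) / (n - 1)
            cov += hyper * (np.diag(frac) - np.outer(frac, frac))

    obs_d = {label: float(o) for label, o in zip(labels, observed)}
    exp_d = {label: float(x) for label, x in zip(labels, expected)}
    if len(event_times) == 0:
        logger.warning("log-rank: no events in either group")
        return LogRankResult(0.0, 1.0, k - 1, obs_d, exp_d, flagged=True)

    u = (observed - expected)[:-1]
    sigma = cov[:-1, :-1]
    if k == 2:
        v = float(sigma[0, 0])
        stat = 0.0 if v <= 0 else float(u[0] ** 2 / v)
        flagged = v <= 0
    else:
        stat = float(u @ np.linalg.pinv(sigma) @ u)
        flagged = False
    p = float(_st.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    return LogRankResult(statistic=max(stat, 0.0), p_value=min(max(p, 0.0), 1.0),
                         df=k - 1, observed=obs_d, expected=exp_d, flagged=flagged)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    table: pd.DataFrame  # index covariate; columns coef, hr, se, p
    converged: bool
    n_iter: int
    loglik: float
    flag: str = ""


def cox_ph(times: Sequence[float], events: Sequence[bool],
           covariates: pd.DataFrame, max_iter: int = 100,
           tol: float = 1e-8) -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson on the Breslow
    partial likelihood.

    Convergence: gradient max-norm < ``tol`` (default 1e-8) or ``max_iter``
    iterations.  Constant covariates carry no information and are reported
    with coef 0 / HR 1; a rank-deficient design or a monotone likelihood
    (complete separation) is flagged rather than raising.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(np.asarray(covariates, dtype=float))
    if covariates.isna().to_numpy().any():
        raise ValidationError("missing covariate values")
    if len(t) != len(covariates):
        raise ValidationError("times and covariate rows must match")
    if e.sum() < 1:
        raise ValidationError("Cox model needs at least one event")

    names = [str(c) for c in covariates.columns]
    x_full = covariates.to_numpy(dtype=float)
    const = x_full.std(axis=0) == 0
    active = ~const
    empty = pd.DataFrame(index=names, columns=["coef", "hr", "se", "p"], dtype=float)

    def _finish(beta, se, p, converged, n_iter, loglik, flag=""):
        tab = empty.copy()
        tab.loc[:, :] = np.nan
        tab.loc[np.array(names)[const], ["coef", "hr", "p"]] = [0.0, 1.0, 1.0]
        act_names = np.array(names)[active]
        if len(act_names):
            tab.loc[act_names, "coef"] = beta
            tab.loc[act_names, "hr"] = np.exp(beta)
            tab.loc[act_names, "se"] = se
            tab.loc[act_names, "p"] = p
        return CoxResult(table=tab, converged=converged, n_iter=n_iter,
                         loglik=loglik, flag=flag)

    if not active.any():
        return _finish(np.array([]), np.array([]), np.array([]), True, 0, float("nan"))

    x = x_full[:, active]
    x = x - x.mean(axis=0)  # centering improves conditioning; coefs unchanged
    p_act = x.shape[1]
    if np.linalg.matrix_rank(x) < p_act:
        logger.warning("cox_ph: rank-deficient covariate matrix")
        nan = np.full(p_act, np.nan)
        return _finish(nan, nan, nan, False, 0, float("nan"), flag="rank_deficient")

    order = np.argsort(t, kind="stable")
    t_s, e_s, x_s = t[order], e[order], x[order]
    event_times = np.unique(t_s[e_s])

    def loglik_grad_hess(beta):
        eta = x_s @ beta
        eta -= eta.max()  # guard overflow; cancels in the ratios below
        w = np.exp(eta)
        ll = 0.0
        grad = np.zeros(p_act)
        hess = np.zeros((p_act, p_act))
        for tt in event_times:
            risk = t_s >= tt
            dead = e_s & (t_s == tt)
            d = int(dead.sum())
            s0 = w[risk].sum()
            s1 = w[risk] @ x_s[risk]
            s2 = (w[risk][:, None] * x_s[risk]).T @ x_s[risk]
            ll += eta[dead].sum() - d * np.log(s0)
            grad += x_s[dead].sum(axis=0) - d * s1 / s0
            hess += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
        return ll, grad, hess

    beta = np.zeros(p_act)
    ll, grad, hess = loglik_grad_hess(beta)
    converged = False
    flag = ""
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            flag = "singular_hessian"
            break
        # step halving
        new_beta = beta + step
        new_ll, new_grad, new_hess = loglik_grad_hess(new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = loglik_grad_hess(new_beta)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > 50:
            flag = "monotone_likelihood"
            logger.warning("cox_ph: coefficients diverging; likely complete separation")
            break
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
    if not converged and not flag:
        flag = "max_iter"
        logger.warning("cox_ph: no convergence in %d iterations", max_iter)

    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p_act, np.nan)
    # a monotone partial likelihood lets the gradient vanish at huge
    # coefficients with exploding standard errors; flag it as non-convergence
    if converged and (np.any(np.abs(beta) > 30)
                      or np.any(se > 100.0 * (1.0 + np.abs(beta)))):
        converged = False
        flag = "monotone_likelihood"
        logger.warning("cox_ph: degenerate fit (likely complete separation)")
    with np.errstate(divide="ignore", invalid="ignore"):
        zed = beta / se
    pvals = 2.0 * _st.norm.sf(np.abs(zed))
    return _finish(beta, se, pvals, converged, it, float(ll), flag=flag)


# ---------------------------------------------------------------------------
# Two-sample t-test
# ---------------------------------------------------------------------------

def two_sample_t(values_a: Sequence[float], values_b: Sequence[float],
                 variant: str = "welch") -> dict:
    """Two-sided two-sample t-test (Welch default, pooled optional)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least two values")
    if variant not in ("welch", "pooled"):
        raise ValidationError(f"unknown variant {variant!r}")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    flagged = False
    if va == 0 and vb == 0:
        flagged = True
        if ma == mb:
            return {"t": 0.0, "df": float(na + nb - 2), "p": 1.0, "flagged": flagged}
        t_stat = float(np.inf) if ma > mb else float(-np.inf)
        return {"t": t_stat, "df": float(na + nb - 2), "p": 0.0, "flagged": flagged}
    if variant == "welch":
        se2 = va / na + vb / nb
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = na + nb - 2
    t_stat = float((ma - mb) / np.sqrt(se2))
    p = float(2.0 * _st.t.sf(abs(t_stat), df))
    return {"t": t_stat, "df": float(df), "p": p, "flagged": flagged}
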