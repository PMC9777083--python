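"""Survival-statistics kernel.

Cox proportional-hazards fitting (Breslow ties, Newton-Raphson with
step-halving), Harrell's concordance index, Kaplan-Meier / log-rank
comparison, Benjamini-Hochberg adjustment, exact 2x2 Fisher tests with
odds ratios, and IPCW cumulative/dynamic time-dependent AUC.

The Cox fitter is implemented here rather than delegated because the
screening stages fit the model tens of thousands of times on single
covariates (often binary pair indicators): a degenerate covariate must
yield a flagged, non-significant result rather than an exception, and a
vectorized batch path over many binary covariates is needed for pair
screening. ``lifelines`` backs the Kaplan-Meier/log-rank operations and
serves as an independent cross-check of the Cox fitter in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxFit",
    "ContingencyResult",
    "KMResult",
    "cox_fit",
    "cox_fit_multivariate",
    "cox_fit_binary_batch",
    "concordance_index",
    "bh_adjust",
    "km_logrank",
    "fisher_2x2",
    "td_auc",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class CoxFit:
    """Result of a Cox proportional-hazards fit for one covariate.

    ``hr`` is ``exp(coef)``; ``p`` is the Wald p-value; ``ci_low`` and
    ``ci_high`` bound the 95% confidence interval of the hazard ratio.
    ``converged=False`` marks degenerate inputs (constant covariate,
    fewer than two events, monotone-likelihood separation); such fits
    carry ``p=1`` so that screening loops skip them gracefully.
    """

    coef: float
    hr: float
    se: float
    p: float
    ci_low: float
    ci_high: float
    converged: bool


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 contingency table with sample odds ratio and Fisher exact p.

    For table rows (a, b; c, d) the odds ratio is (a*d)/(b*c); the
    two-sided p sums hypergeometric probabilities no larger than that of
    the observed table.
    """

    table: np.ndarray
    odds_ratio: float
    p: float

    @property
    def reciprocal_odds_ratio(self) -> float:
        return 1.0 / self.odds_ratio


@dataclass
class KMResult:
    """Kaplan-Meier curves per group and the two-group log-rank p."""

    curves: dict = field(default_factory=dict)  # label -> DataFrame(timeline, survival)
    logrank_p: float = float("nan")


def _as_float_arrays(*arrays):
    return tuple(np.asarray(a, dtype=float).ravel() for a in arrays)


def _degenerate_fit(p_dim: int = 1):
    fit = CoxFit(coef=0.0, hr=1.0, se=np.inf, p=1.0,
                 ci_low=0.0, ci_high=np.inf, converged=False)
    return fit if p_dim == 1 else [fit] * p_dim


def _breslow_loglik_terms(time: np.ndarray, event: np.ndarray):
    """Sort ascending by time and locate tie groups / event counts.

    Returns (order, group_start, d_k, event_mask_sorted) where
    ``group_start[k]`` is the first sorted index of the k-th distinct
    event time (risk set = samples from that index onward) and ``d_k``
    the number of events at that time.
    """
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order].astype(bool)
    event_times = np.unique(t_sorted[e_sorted])
    group_start = np.searchsorted(t_sorted, event_times, side="left")
    # events per distinct event time
    d_k = np.array([np.sum(e_sorted[t_sorted == t]) for t in event_times], dtype=float)
    return order, group_start, d_k, e_sorted


def _cox_newton(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                max_iter: int = 50, tol: float = 1e-9):
    """Maximize the Breslow partial likelihood by damped Newton-Raphson.

    Returns (beta, cov, converged, loglik)."""
    n, p = X.shape
    order, group_start, d_k, e_sorted = _breslow_loglik_terms(time, event)
    Xs = X[order]
    x_events_sum = Xs[e_sorted].sum(axis=0)

    def ll_grad_hess(beta):
        eta = Xs @ beta
        eta = eta - eta.max()  # stabilize; constant shift cancels in all ratios
        w = np.exp(eta)
        # reverse cumulative sums -> risk-set aggregates at each group start
        s0 = np.cumsum(w[::-1])[::-1][group_start]
        s1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1][group_start]
        s2 = np.cumsum((w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1],
                       axis=0)[::-1][group_start]
        ll = float(e_sorted @ eta - d_k @ np.log(s0))
        mean_k = s1 / s0[:, None]
        grad = x_events_sum - d_k @ mean_k
        hess = -(np.einsum("k,kij->ij", d_k, s2 / s0[:, None, None])
                 - np.einsum("k,ki,kj->ij", d_k, mean_k, mean_k))
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = ll_grad_hess(beta)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            return beta, None, False, ll
        # step-halving line search
        new_beta, new = beta + step, None
        for _half in range(30):
            new = ll_grad_hess(new_beta)
            if new[0] >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        if new is None:  # pragma: no cover
            break
        delta = float(np.max(np.abs(new_beta - beta)))
        beta, (ll, grad, hess) = new_beta, new
        if delta < tol or np.max(np.abs(grad)) < tol:
            converged = True
            break
    # a huge coefficient or a flat information surface marks monotone
    # likelihood (separation): no finite MLE exists
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 10:
        converged = False
    try:
        cov = np.linalg.inv(-hess)
        if np.any(np.diag(cov) <= 0):
            cov = None
    except np.linalg.LinAlgError:
        cov = None
    return beta, cov, converged and cov is not None, ll


def _fits_from_newton(beta, cov, converged) -> list[CoxFit]:
    fits = []
    for j, b in enumerate(beta):
        if cov is None:
            fits.append(CoxFit(coef=float(b), hr=float(np.exp(b)), se=np.inf,
                               p=1.0, ci_low=0.0, ci_high=np.inf, converged=False))
            continue
        se = float(np.sqrt(cov[j, j]))
        z = b / se if se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        with np.errstate(over="ignore"):
            fits.append(CoxFit(
                coef=float(b), hr=float(np.exp(b)), se=se,
                p=p if converged else 1.0,
                ci_low=float(np.exp(b - _Z975 * se)),
                ci_high=float(np.exp(b + _Z975 * se)),
                converged=converged,
            ))
    return fits


def cox_fit(x, time, event, max_iter: int = 50) -> CoxFit:
    """Univariate Cox PH fit of covariate ``x`` against right-censored survival.

    Breslow tie handling; Wald p-value and 95% CI on the hazard ratio.
    Degenerate inputs (constant ``x``, fewer than 2 events) return a
    flagged non-converged fit with ``p=1`` instead of raising, so that
    genome-scale screening loops can skip them.
    """
    x, time, event = _as_float_arrays(x, time, event)
    if x.size != time.size or time.size != event.size:
        raise ValueError("x, time and event must have equal length")
    if event.sum() < 2 or np.ptp(x) == 0 or not np.all(np.isfinite(x)):
        return _degenerate_fit()
    beta, cov, converged, _ = _cox_newton(x[:, None], time, event, max_iter=max_iter)
    return _fits_from_newton(beta, cov, converged)[0]


def cox_fit_multivariate(X, time, event, max_iter: int = 50) -> list[CoxFit]:
    """Multivariate Cox PH fit; returns one :class:`CoxFit` per column of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x covariates)")
    time, event = _as_float_arrays(time, event)
    if event.sum() < 2 or np.any(np.ptp(X, axis=0) == 0):
        return _degenerate_fit(X.shape[1])
    beta, cov, converged, _ = _cox_newton(X, time, event, max_iter=max_iter)
    return _fits_from_newton(beta, cov, converged)


def cox_fit_binary_batch(X01: np.ndarray, time, event, max_iter: int = 40,
                         tol: float = 1e-10):
    """Fit many univariate Cox models with binary covariates at once.

    ``X01`` is (m features x n samples) in {0,1}. Exploits x^2 = x: the
    risk-set aggregates reduce to counts of x=1 carriers, so the Newton
    iteration is a closed-form scalar update vectorized across features.

    Returns dict of arrays: coef, se, p, converged (all length m).
    """
    X01 = np.asarray(X01)
    time, event = _as_float_arrays(time, event)
    m, n = X01.shape
    order, group_start, d_k, e_sorted = _breslow_loglik_terms(time, event)
    Xs = X01[:, order].astype(float)
    n1_k = np.cumsum(Xs[:, ::-1], axis=1)[:, ::-1][:, group_start]  # (m, K)
    n_risk = np.cumsum(np.ones(n)[::-1])[::-1][group_start]         # (K,)
    e1 = Xs[:, e_sorted].sum(axis=1)                                # (m,)

    valid = (Xs.sum(axis=1) > 0) & (Xs.sum(axis=1) < n) & (event.sum() >= 2)
    beta = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    info = np.full(m, np.nan)
    active = valid.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        eb = np.exp(beta[active])[:, None]
        s1_over_s0 = n1_k[active] * eb / ((n_risk - n1_k[active]) + n1_k[active] * eb)
        grad = e1[active] - s1_over_s0 @ d_k
        cur_info = (s1_over_s0 * (1.0 - s1_over_s0)) @ d_k
        ok = cur_info > 1e-12
        step = np.zeros_like(grad)
        step[ok] = grad[ok] / cur_info[ok]
        np.clip(step, -2.0, 2.0, out=step)  # damping against overshoot
        idx = np.flatnonzero(active)
        beta[idx] += step
        info[idx] = cur_info
        done = (np.abs(step) < tol) | ~ok
        converged[idx[done]] = True
        active[idx[done]] = False
    diverged = np.abs(beta) > 10
    converged &= ~diverged & valid
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(converged & (info > 0), 1.0 / np.sqrt(info), np.inf)
        z = np.where(np.isfinite(se), beta / se, 0.0)
    p = np.where(converged, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return {"coef": beta, "se": se, "p": p, "converged": converged}


def concordance_index(score, time, event) -> float:
    """Harrell's concordance index of a risk score under right censoring.

    A pair (i, j) is comparable when ``time_i < time_j`` and sample i's
    event was observed; censored-censored pairs and pairs tied on time
    are not comparable. Concordant means the shorter-surviving sample
    carries the strictly higher score; score ties count 1/2.
    """
    score, time, event = _as_float_arrays(score, time, event)
    n = score.size
    if not (time.size == n == event.size):
        raise ValueError("score, time, event must have equal length")
    shorter = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    n_comp = int(shorter.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs: data carry no survival ordering "
                         "information for the concordance index")
    conc = np.sum(shorter & (score[:, None] > score[None, :]))
    ties = np.sum(shorter & (score[:, None] == score[None, :]))
    return float((conc + 0.5 * ties) / n_comp)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def km_logrank(time, event, group) -> KMResult:
    """Kaplan-Meier curves per group plus the two-group log-rank test p-value."""
    time, event = _as_float_arrays(time, event)
    group = np.asarray(group).ravel()
    labels = pd.unique(group)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(labels)}")
    result = KMResult()
    masks = {}
    for lab in labels:
        mask = group == lab
        if mask.sum() == 0:  # pragma: no cover - unique() precludes this
            raise ValueError(f"group {lab!r} is empty")
        masks[lab] = mask
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask], label=str(lab))
        result.curves[lab] = kmf.survival_function_
    a, b = labels
    lr = logrank_test(time[masks[a]], time[masks[b]],
                      event_observed_A=event[masks[a]],
                      event_observed_B=event[masks[b]])
    result.logrank_p = float(lr.p_value)
    return result


def fisher_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-sided Fisher exact test of the 2x2 table (a, b; c, d).

    The p-value sums hypergeometric probabilities not exceeding that of
    the observed table; the odds ratio is the sample estimate (a*d)/(b*c).
    """
    cells = [a, b, c, d]
    if any(v < 0 or v != int(v) for v in cells):
        raise ValueError("table cells must be non-negative integers")
    table = np.array([[a, b], [c, d]], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        orr = (a * d) / (b * c) if b * c > 0 else np.inf
    p = float(stats.fisher_exact(table)[1])
    return ContingencyResult(table=table, odds_ratio=float(orr), p=p)


def _censoring_km(time: np.ndarray, event: np.ndarray):
    """KM estimate G of the censoring survival function (censoring as event).

    Returns a step-function evaluator ``G(t, left=False)``; with
    ``left=True`` it yields the left limit G(t-)."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    cens = 1.0 - e
    uniq = np.unique(t)
    n_at_risk = t.size - np.searchsorted(t, uniq, side="left")
    d_cens = np.array([cens[t == u].sum() for u in uniq])
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(n_at_risk > 0, 1.0 - d_cens / n_at_risk, 1.0)
    surv = np.cumprod(factors)

    def G(q, left=False):
        side = "left" if left else "right"
        idx = np.searchsorted(uniq, q, side=side) - 1
        idx = np.atleast_1d(idx)
        out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return out if np.ndim(q) else float(out[0])

    return G


def td_auc(score, time, event, horizon: float) -> float:
    """IPCW cumulative/dynamic AUC of a risk score at a fixed horizon.

    Cases are samples with an observed event by ``horizon``; controls are
    samples still under observation beyond it. Censoring is handled by
    weighting cases by 1/G(T-) and controls by 1/G(horizon), with G the
    Kaplan-Meier estimate of the censoring survival function. With no
    censoring every weight is 1 and the value reduces to the plain AUC
    (Mann-Whitney statistic) of the dichotomized outcome.
    """
    score, time, event = _as_float_arrays(score, time, event)
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError(f"no cases or no controls at horizon {horizon}")
    G = _censoring_km(time, event)
    w_case = 1.0 / np.asarray(G(time[case], left=True), dtype=float)
    g_h = G(horizon)
    if g_h <= 0 or not np.all(np.isfinite(w_case)):
        raise ValueError(f"censoring distribution vanishes before horizon {horizon}")
    w_ctrl = np.full(int(control.sum()), 1.0 / g_h)
    s_case, s_ctrl = score[case], score[control]
    gt = (s_case[:, None] > s_ctrl[None, :]).astype(float)
    gt += 0.5 * (s_case[:, None] == s_ctrl[None, :])
    num = float(w_case @ gt @ w_ctrl)
    den = float(w_case.sum() * w_ctrl.sum())
    return num / den
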