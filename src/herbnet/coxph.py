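"""Cox proportional-hazards engine, Kaplan-Meier estimator and log-rank test.

The Cox model relates a covariate vector x to the hazard through
``h(t | x) = h0(t) * exp(beta' x)``.  ``beta`` is estimated by
Newton-Raphson maximisation of the partial likelihood with Efron's
approximation for tied event times; standard errors come from the
observed information, giving per-covariate Wald tests, hazard ratios
``exp(beta)`` and 95 % confidence intervals.

Convergence is declared when the score (gradient) falls below 1e-9 in
max-norm, within at most 50 iterations.  A monotone partial likelihood
(perfect separation driving a coefficient to infinity) is reported as a
non-converged fit rather than an arbitrary large coefficient.

The module also provides the product-limit (Kaplan-Meier) survival
estimator and the two-group log-rank test: at every event time the
observed event count in group 1 is compared with its hypergeometric
expectation under the null, and ``(O - E)^2 / V`` is referred to a
chi-square with one degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CoxFit",
    "cox_fit",
    "cox_score_test",
    "kaplan_meier",
    "logrank_test",
    "ConvergenceWarning",
]

MAX_ITER = 50
SCORE_TOL = 1e-9
#: |beta| beyond which the likelihood is treated as monotone
_BETA_DIVERGED = 200.0


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model."""

    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    converged: bool
    n_iter: int
    information: np.ndarray = field(repr=False, default=None)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        """95 % Wald confidence bounds on the hazard ratios."""
        z = stats.norm.ppf(0.975)
        return np.exp(self.beta - z * self.se), np.exp(self.beta + z * self.se)

    @property
    def p(self) -> np.ndarray:
        """Per-covariate two-sided Wald p-values."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.beta / self.se, np.inf)
        return 2.0 * stats.norm.sf(np.abs(z))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.beta)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta

    def summary(self) -> dict:
        lo, hi = self.ci
        return {
            "covariates": list(self.covariates),
            "beta": self.beta.tolist(),
            "hr": self.hr.tolist(),
            "ci_low": lo.tolist(),
            "ci_high": hi.tolist(),
            "se": self.se.tolist(),
            "p": self.p.tolist(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "aic": self.aic,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
        }


def _validate(time, event, X):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.any(time <= 0):
        raise ValueError("follow-up times must be positive")
    if not set(np.unique(event)) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    event = event.astype(bool)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    spread = X.max(axis=0) - X.min(axis=0)
    if np.any(spread == 0):
        const = [i for i, s in enumerate(spread) if s == 0]
        raise ValueError(f"constant covariate(s) at column(s) {const}")
    return time, event, X


def _efron_quantities(time, event, X, beta):
    """Log partial likelihood, score vector and observed information.

    Fully vectorised: suffix sums give the risk-set aggregates per
    distinct event time, ``np.add.reduceat`` the tied-event aggregates,
    and the Efron within-tie corrections are expanded into one flat
    array over all events.
    """
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    t, d, x = time[order], event[order], X[order]
    eta = x @ beta
    eta = eta - eta.max()  # guard exp overflow; cancels in all ratios
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = wx[:, :, None] * x[:, None, :]
    # suffix sums: the risk set at the i-th smallest time is positions i..n-1
    s_w = np.cumsum(w[::-1])[::-1]
    s_wx = np.cumsum(wx[::-1], axis=0)[::-1]
    s_wxx = np.cumsum(wxx[::-1], axis=0)[::-1]

    # first position of each distinct time, and the event count per group
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    group_of = np.cumsum(np.r_[True, t[1:] != t[:-1]]) - 1
    n_groups = len(starts)
    d_count = np.zeros(n_groups, dtype=int)
    np.add.at(d_count, group_of[d], 1)
    ev = np.flatnonzero(d_count)  # groups containing events
    if len(ev) == 0:
        return 0.0, np.zeros(p), np.zeros((p, p))

    dmask = d.astype(bool)
    ecount = np.where(dmask, 1.0, 0.0)
    # tied-event aggregates per group (reduceat over the sorted arrays)
    s_d = np.add.reduceat(w * ecount, starts)[ev]
    z_d = np.add.reduceat(wx * ecount[:, None], starts, axis=0)[ev]
    q_d = np.add.reduceat(wxx * ecount[:, None, None], starts, axis=0)[ev]
    dd = d_count[ev]

    loglik = float(eta[dmask].sum())
    score = x[dmask].sum(axis=0)

    # expand the Efron corrections: one row per event (l = 0..d-1 per group)
    reps = np.repeat(np.arange(len(ev)), dd)
    frac = (np.concatenate([np.arange(k) for k in dd]) /
            np.repeat(dd, dd))
    phi = s_w[starts[ev]][reps] - frac * s_d[reps]
    zl = s_wx[starts[ev]][reps] - frac[:, None] * z_d[reps]
    ql = s_wxx[starts[ev]][reps] - frac[:, None, None] * q_d[reps]
    loglik -= float(np.log(phi).sum())
    u = zl / phi[:, None]
    score -= u.sum(axis=0)
    info = (ql / phi[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", u, u)
    return loglik, score, info


def cox_fit(time, event, X, covariates: list[str] | None = None) -> CoxFit:
    """Fit a Cox model by Newton-Raphson on the Efron partial likelihood.

    ``X`` is samples x covariates (a single covariate may be 1-D).
    Raises ``ValueError`` for constant covariates or fewer than two
    events; a monotone likelihood is flagged via ``converged=False``
    with a :class:`ConvergenceWarning`.
    """
    time, event, X = _validate(time, event, X)
    n, p = X.shape
    if covariates is None:
        covariates = [f"x{i}" for i in range(p)]
    # centre covariates for numerical stability; beta is unaffected
    centre = X.mean(axis=0)
    Xc = X - centre

    loglik_null, _, _ = _efron_quantities(time, event, Xc, np.zeros(p))
    beta = np.zeros(p)
    loglik = loglik_null
    converged = False
    diverged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        loglik, score, info = _efron_quantities(time, event, Xc, beta)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            diverged = True
            break
        # step-halve when the likelihood fails to improve
        new = beta + step
        ll_new, _, _ = _efron_quantities(time, event, Xc, new)
        halves = 0
        while ll_new < loglik - 1e-12 and halves < 20:
            step *= 0.5
            new = beta + step
            ll_new, _, _ = _efron_quantities(time, event, Xc, new)
            halves += 1
        beta = new
        if np.max(np.abs(beta)) > _BETA_DIVERGED:
            diverged = True
            break
    loglik, score, info = _efron_quantities(time, event, Xc, beta)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    # a flat likelihood plateau (huge standard error next to the attained
    # coefficient) is the numerical signature of a monotone likelihood
    if np.any(~np.isfinite(se)) or np.any(se > 100.0 * (1.0 + np.abs(beta))):
        diverged = True
    if diverged or not converged:
        warnings.warn(
            "Cox partial likelihood did not converge (possible monotone "
            "likelihood / perfect separation)", ConvergenceWarning)
    return CoxFit(
        covariates=list(covariates), beta=beta, se=se,
        loglik=float(loglik), loglik_null=float(loglik_null),
        n=n, n_events=int(event.sum()),
        converged=bool(converged and not diverged), n_iter=it,
        information=info,
    )


def cox_score_test(time, event, X) -> tuple[float, float]:
    """Cox score (Rao) test at beta = 0: ``U' I^{-1} U ~ chi2(p)``."""
    time, event, X = _validate(time, event, X)
    Xc = X - X.mean(axis=0)
    _, score, info = _efron_quantities(time, event, Xc, np.zeros(X.shape[1]))
    stat = float(score @ np.linalg.solve(info, score))
    return stat, float(stats.chi2.sf(stat, X.shape[1]))


def kaplan_meier(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate.

    Returns the distinct event times and the survival probability just
    after each (a right-continuous step function starting from 1).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    n = len(t)
    out_t, out_s = [], []
    surv = 1.0
    i = 0
    while i < n:
        j = i
        deaths = 0
        while j < n and t[j] == t[i]:
            deaths += int(d[j])
            j += 1
        at_risk = n - i
        if deaths:
            surv *= 1.0 - deaths / at_risk
            out_t.append(t[i])
            out_s.append(surv)
        i = j
    return np.array(out_t), np.array(out_s)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time, with ``n`` at risk overall, ``n1`` at
    risk in group 1, and ``d`` events of which ``d1`` in group 1:
    ``O - E`` accumulates ``d1 - d n1/n`` and the variance accumulates
    the hypergeometric term ``d n1 (n - n1) (n - d) / (n^2 (n - 1))``.
    Returns the chi-square statistic (1 df) and its p-value; identical
    groups give statistic 0 and p = 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError("log-rank test needs exactly two groups")
    g1 = group == labels[1]

    order = np.argsort(time, kind="stable")
    t, d, g = time[order], event[order], g1[order]
    n_total = len(t)
    suffix1 = np.cumsum(g[::-1])[::-1]
    o_minus_e = 0.0
    var = 0.0
    i = 0
    while i < n_total:
        j = i
        deaths = deaths1 = 0
        while j < n_total and t[j] == t[i]:
            deaths += int(d[j])
            deaths1 += int(d[j] and g[j])
            j += 1
        at_risk = n_total - i
        at_risk1 = int(suffix1[i])
        if deaths and at_risk > 1:
            o_minus_e += deaths1 - deaths * at_risk1 / at_risk
            var += (deaths * at_risk1 * (at_risk - at_risk1)
                    * (at_risk - deaths)) / (at_risk ** 2 * (at_risk - 1))
        i = j
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e ** 2 / var
    return float(stat), float(stats.chi2.sf(stat, 1))
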