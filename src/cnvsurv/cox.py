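"""Left-truncated Cox proportional-hazards engine.

All association tests in the pipeline (per-marker scans, region trend and
categorical tests, genome-wide burden) reduce to a Cox model with delayed
entry: a subject enters the risk set only at enrollment, so the risk set at
event time ``t`` is ``R(t) = {i : entry_i < t <= exit_i}``.  Ignoring the
entry times would condition on having survived to enrollment and bias hazard
ratios toward protective values.

The partial likelihood is maximized by Newton-Raphson with step-halving;
tied event times use the Efron approximation by default (Breslow available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalData",
    "CoxFit",
    "NonIdentifiableError",
    "partial_loglik",
    "fit_cox_left_truncated",
    "test_trend",
    "test_categorical_2df",
    "kaplan_meier",
]


class NonIdentifiableError(ValueError):
    """Raised when a covariate carries no information (constant column)."""


@dataclass(frozen=True)
class SurvivalData:
    """Delayed-entry survival outcomes with a covariate matrix.

    Parameters
    ----------
    entry, exit, event : arrays of shape (n,)
        Days from time origin (diagnosis) to enrollment, to death or last
        follow-up, and the event indicator (1 = death observed).
    X : array of shape (n, p)
        Covariate matrix; by convention the tested variable(s) come first,
        followed by adjustment covariates (site indicators, age at
        diagnosis, ancestry principal components).
    names : tuple of str
        Column names for ``X``.
    """

    entry: np.ndarray
    exit: np.ndarray
    event: np.ndarray
    X: np.ndarray
    names: tuple = ()

    def __post_init__(self):
        entry = np.asarray(self.entry, dtype=float)
        exit_ = np.asarray(self.exit, dtype=float)
        event = np.asarray(self.event, dtype=int)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.shape[0] != entry.shape[0]:
            X = X.T
        if X.size == 0:
            X = np.empty((entry.shape[0], 0))
        object.__setattr__(self, "entry", entry)
        object.__setattr__(self, "exit", exit_)
        object.__setattr__(self, "event", event)
        object.__setattr__(self, "X", X)
        names = tuple(self.names) if self.names else tuple(
            f"x{j}" for j in range(X.shape[1])
        )
        object.__setattr__(self, "names", names)
        if np.any(entry < 0):
            raise ValueError("entry times must be >= 0")
        if np.any(exit_ <= entry):
            bad = int(np.argmax(exit_ <= entry))
            raise ValueError(f"exit must exceed entry for every subject (subject {bad})")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if event.sum() < 1:
            raise ValueError("need at least one observed event")
        if not np.isfinite(X).all():
            raise ValueError("covariates must be finite (no missing values)")

    @property
    def n(self) -> int:
        return self.entry.shape[0]

    def with_tested(self, values, name="tested") -> "SurvivalData":
        """Return a copy with ``values`` prepended as the tested covariate."""
        v = np.asarray(values, dtype=float).reshape(-1, 1)
        return replace(
            self, X=np.hstack([v, self.X]), names=(name,) + tuple(self.names)
        )


@dataclass
class CoxFit:
    """Result of a partial-likelihood maximization."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    hr: np.ndarray
    ci95: np.ndarray  # shape (p, 2)
    p_wald: np.ndarray
    converged: bool
    n_subjects: int
    n_events: int
    names: tuple = ()
    n_iter: int = 0
    separation: bool = False

    def summary(self) -> str:
        lines = ["covariate\tbeta\tse\tHR\tCI95_lo\tCI95_hi\tp_wald"]
        for j, nm in enumerate(self.names):
            lines.append(
                f"{nm}\t{self.beta[j]:.6g}\t{self.se[j]:.6g}\t{self.hr[j]:.6g}"
                f"\t{self.ci95[j, 0]:.6g}\t{self.ci95[j, 1]:.6g}\t{self.p_wald[j]:.3g}"
            )
        return "\n".join(lines)


def _risk_aggregates(beta, entry, exit_, event, X, ties):
    """Log partial likelihood, gradient and Hessian at ``beta``.

    Risk sums at each unique event time t are obtained from two descending
    cumulative sums: sum over {exit >= t} minus sum over {entry >= t}, which
    equals the sum over the delayed-entry risk set {entry < t <= exit}.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # rescaling cancels in all ratios; guards overflow
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    dmask = event == 1
    t_ev = exit_[dmask]
    uniq, inv, counts = np.unique(t_ev, return_inverse=True, return_counts=True)
    m = uniq.shape[0]

    # cumulative sums over exits >= t
    order_x = np.argsort(-exit_, kind="stable")
    cx0 = np.concatenate([[0.0], np.cumsum(w[order_x])])
    cx1 = np.vstack([np.zeros(p), np.cumsum(wx[order_x], axis=0)])
    cx2 = np.concatenate([np.zeros((1, p, p)), np.cumsum(wxx[order_x], axis=0)])
    exit_desc = exit_[order_x]
    # number of exits >= t  (exit_desc is descending)
    kx = np.searchsorted(-exit_desc, -uniq, side="right")

    # cumulative sums over entries >= t
    order_e = np.argsort(-entry, kind="stable")
    ce0 = np.concatenate([[0.0], np.cumsum(w[order_e])])
    ce1 = np.vstack([np.zeros(p), np.cumsum(wx[order_e], axis=0)])
    ce2 = np.concatenate([np.zeros((1, p, p)), np.cumsum(wxx[order_e], axis=0)])
    entry_desc = entry[order_e]
    ke = np.searchsorted(-entry_desc, -uniq, side="right")

    S0 = cx0[kx] - ce0[ke]
    S1 = cx1[kx] - ce1[ke]
    S2 = cx2[kx] - ce2[ke]

    # per-tie-group sums over the deaths themselves
    ord_d = np.argsort(inv, kind="stable")
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    wd = w[dmask][ord_d]
    wxd = wx[dmask][ord_d]
    wxxd = wxx[dmask][ord_d]
    D0 = np.add.reduceat(wd, starts)
    D1 = np.add.reduceat(wxd, starts, axis=0)
    D2 = np.add.reduceat(wxxd, starts, axis=0)
    xsum_d = np.add.reduceat(X[dmask][ord_d], starts, axis=0)
    etasum_d = np.add.reduceat(eta[dmask][ord_d], starts)

    if ties == "breslow":
        frac = np.zeros(m)
        rep = np.ones(m, dtype=int)
        dmult = counts.astype(float)
    elif ties == "efron":
        rep = counts
        # l/d for l = 0..d-1 within each group
        l = np.concatenate([np.arange(d) for d in counts]).astype(float)
        frac = l / np.repeat(counts, rep).astype(float)
        dmult = np.ones(int(counts.sum()))
    else:
        raise ValueError(f"unknown ties method {ties!r}")

    g = np.repeat(np.arange(m), rep)
    den0 = np.repeat(S0, rep) - frac * D0[g]
    if np.any(den0 <= 0) or not np.isfinite(den0).all():
        return -np.inf, np.zeros(p), np.zeros((p, p))
    den1 = np.repeat(S1, rep, axis=0) - frac[:, None] * D1[g]
    den2 = np.repeat(S2, rep, axis=0) - frac[:, None, None] * D2[g]

    loglik = float(etasum_d.sum() - (dmult * np.log(den0)).sum())
    mu = den1 / den0[:, None]
    grad = xsum_d.sum(axis=0) - (dmult[:, None] * mu).sum(axis=0)
    v = den2 / den0[:, None, None] - mu[:, :, None] * mu[:, None, :]
    hess = -(dmult[:, None, None] * v).sum(axis=0)
    return loglik, grad, hess


def partial_loglik(beta, data: SurvivalData, ties: str = "efron") -> float:
    """Delayed-entry partial log-likelihood at ``beta`` (oracle-friendly)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll, _, _ = _risk_aggregates(beta, data.entry, data.exit, data.event, data.X, ties)
    return ll


def fit_cox_left_truncated(
    data: SurvivalData,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
    beta_max: float = 15.0,
) -> CoxFit:
    """Maximize the delayed-entry partial likelihood by Newton-Raphson.

    Convergence is declared when the relative change in log partial
    likelihood falls below ``tol``.  Monotone likelihoods (complete
    separation) are flagged: the fit is returned non-converged with the
    diverging coefficient visible and its Wald p set to NaN.
    """
    X = data.X
    n, p = X.shape
    if p == 0:
        raise NonIdentifiableError("no covariates to fit")
    sd = X.std(axis=0)
    if np.any(sd < 1e-12):
        j = int(np.argmin(sd))
        raise NonIdentifiableError(
            f"non-identifiable covariate: column {data.names[j]!r} is constant"
        )
    # center columns for conditioning; Cox estimates are shift-invariant
    xbar = X.mean(axis=0)
    Xc = X - xbar

    beta = np.zeros(p)
    ll, grad, hess = _risk_aggregates(beta, data.entry, data.exit, data.event, Xc, ties)
    ll_null = ll
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        beta_new = beta - step
        ll_new, g_new, h_new = _risk_aggregates(
            beta_new, data.entry, data.exit, data.event, Xc, ties
        )
        halvings = 0
        while (not np.isfinite(ll_new) or ll_new < ll) and halvings < 30:
            step = step / 2.0
            beta_new = beta - step
            ll_new, g_new, h_new = _risk_aggregates(
                beta_new, data.entry, data.exit, data.event, Xc, ties
            )
            halvings += 1
        if not np.isfinite(ll_new):
            separation = True
            break
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        beta, ll, grad, hess = beta_new, ll_new, g_new, h_new
        if np.any(np.abs(beta) > beta_max):
            separation = True
            break
        if rel < tol:
            converged = True
            break

    info = -hess
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(info)
            var = np.diag(cov)
        except np.linalg.LinAlgError:
            var = np.full(p, np.nan)
    if np.any(~np.isfinite(var)) or np.any(var < 0):
        separation = separation or True
        var = np.where(np.isfinite(var) & (var >= 0), var, np.nan)
    se = np.sqrt(var)
    if separation:
        converged = False
    with np.errstate(all="ignore"):
        z = beta / se
        p_wald = 2.0 * stats.norm.sf(np.abs(z))
        hr = np.exp(beta)
        ci = np.column_stack([np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)])
    if separation:
        p_wald = np.full(p, np.nan)
        warnings.warn(
            "monotone partial likelihood (separation) detected; "
            f"|beta| = {np.max(np.abs(beta)):.3g}, p-values set to NaN",
            stacklevel=2,
        )
    return CoxFit(
        beta=beta,
        se=se,
        loglik=ll,
        loglik_null=ll_null,
        hr=hr,
        ci95=ci,
        p_wald=p_wald,
        converged=converged,
        n_subjects=n,
        n_events=int(data.event.sum()),
        names=data.names,
        n_iter=it,
        separation=separation,
    )


def test_trend(states, data: SurvivalData, ties: str = "efron"):
    """1-df trend test: copy state (-1/0/+1 or continuous) as one covariate.

    Returns ``(CoxFit, p)`` where p is the Wald p-value of the state term.
    """
    states = np.asarray(states, dtype=float)
    if states.std() < 1e-12:
        raise NonIdentifiableError("state variable is constant; trend test undefined")
    fit = fit_cox_left_truncated(data.with_tested(states, "state"), ties=ties)
    return fit, float(fit.p_wald[0])


def test_categorical_2df(states, data: SurvivalData, ties: str = "efron"):
    """Categorical copy-state test: gain and loss indicators vs normal.

    Likelihood-ratio test with df equal to the number of non-reference
    levels present (2 when both gains and losses occur).  Returns
    ``(fit, p, df)``.
    """
    states = np.asarray(states)
    levels = [s for s in (-1, 1) if np.any(states == s)]
    if len(levels) == 0 or len(np.unique(states)) < 2:
        raise NonIdentifiableError("fewer than two state levels present")
    cols = [(states == s).astype(float) for s in levels]
    names = tuple({-1: "loss", 1: "gain"}[s] for s in levels)
    d = replace(
        data,
        X=np.hstack([np.column_stack(cols), data.X]),
        names=names + tuple(data.names),
    )
    fit = fit_cox_left_truncated(d, ties=ties)
    if data.X.shape[1] > 0:
        fit0 = fit_cox_left_truncated(data, ties=ties)
        ll0 = fit0.loglik
    else:
        ll0 = fit.loglik_null
    lrt = 2.0 * (fit.loglik - ll0)
    df = len(levels)
    p = float(stats.chi2.sf(max(lrt, 0.0), df))
    return fit, p, df


def kaplan_meier(states, data: SurvivalData):
    """Delayed-entry product-limit survival estimates per copy state.

    A subject contributes to the risk set at time t only if
    ``entry < t <= exit``.  Returns ``{state: (times, survival)}``; empty
    state groups are omitted with a warning.
    """
    states = np.asarray(states)
    out = {}
    for s in np.unique(states):
        mask = states == s
        if not mask.any():
            warnings.warn(f"state group {s} empty; omitted", stacklevel=2)
            continue
        entry = data.entry[mask]
        exit_ = data.exit[mask]
        event = data.event[mask]
        t_ev = np.unique(exit_[event == 1])
        surv = np.ones(t_ev.shape[0])
        S = 1.0
        for k, t in enumerate(t_ev):
            at_risk = np.sum((entry < t) & (t <= exit_))
            d = np.sum((exit_ == t) & (event == 1))
            if at_risk > 0:
                S *= 1.0 - d / at_risk
            surv[k] = S
        out[int(s) if float(s).is_integer() else s] = (t_ev, surv)
    return out
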