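"""Survival machinery: Kaplan-Meier, log-rank, Cox PH, node ratio.

The Cox model maximises the partial likelihood by Newton-Raphson with
step-halving, handles tied event times with the Efron correction
(Breslow selectable), and offers a cluster-robust sandwich covariance
built from score residuals summed within clusters (matched pairs).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

__all__ = [
    "KMCurve", "SurvivalFit", "ConvergenceError",
    "kaplan_meier", "log_rank", "fit_cox", "robust_cluster_variance",
    "hazard_ratio_ci", "node_ratio", "median_follow_up",
]


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray   # distinct censoring times (curve marks)

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation S(t); S(0-)=1."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.times) == 0:
            return np.ones(t.shape)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk, "events": self.n_events})


def kaplan_meier(times, events) -> KMCurve:
    """Product-limit survival estimate.

    Subjects censored at an event time are counted as still at risk for
    that event (events processed first at tied times).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise ValueError("survival times must be >= 0")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = len(t)
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first) if n else np.array([], dtype=int)
    seg_n = np.add.reduceat(np.ones_like(e), first) if n else np.array([], dtype=int)
    at_risk_all = n - np.concatenate([[0], np.cumsum(seg_n)[:-1]])
    is_event_time = d > 0
    ev_t = uniq[is_event_time]
    ev_d = d[is_event_time]
    ev_r = at_risk_all[is_event_time]
    surv = np.cumprod(1.0 - ev_d / ev_r) if len(ev_t) else np.array([])
    cens = uniq[seg_n - d > 0]
    return KMCurve(times=ev_t, survival=surv, at_risk=ev_r, n_events=ev_d,
                   censor_times=cens)


def log_rank(times, events, group):
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("log_rank requires exactly two groups")
    in1 = g == levels[1]
    o_minus_e = 0.0
    var = 0.0
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int((e == 1)[t == tt].sum())
        d1 = int(((e == 1) & in1 & (t == tt)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e ** 2 / var
    return float(stat), float(chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SurvivalFit:
    names: list[str]
    coef: np.ndarray
    cov: np.ndarray                      # model-based (inverse information)
    robust_cov: np.ndarray | None
    n: int
    n_events: int
    ties: str
    loglik: float
    n_iter: int
    score_residuals: np.ndarray | None = None

    @property
    def se(self) -> np.ndarray:
        c = self.robust_cov if self.robust_cov is not None else self.cov
        return np.sqrt(np.diag(c))

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        hr, lo, hi = hazard_ratio_ci(self, level)
        z = np.where(self.se > 0, self.coef / self.se, 0.0)
        p = 2 * norm.sf(np.abs(z))
        return pd.DataFrame({"term": self.names, "coef": self.coef,
                             "se": self.se, "hr": hr, "ci_lower": lo,
                             "ci_upper": hi, "p": p})


def _pseudo_terms(d_counts, ties):
    """(group index, l/d weight) for every Efron pseudo event term."""
    g_rep = np.repeat(np.arange(len(d_counts)), d_counts)
    offsets = np.concatenate([[0], np.cumsum(d_counts)[:-1]])
    l = np.arange(d_counts.sum()) - np.repeat(offsets, d_counts)
    a = l / np.repeat(d_counts, d_counts) if ties == "efron" else np.zeros(len(l))
    return g_rep, a


def _cox_pass(Xs, ev, first, beta, ties, need_hessian=True):
    """Log-likelihood, gradient and Hessian of the partial likelihood.

    Inputs are pre-sorted by ascending time; ``first`` marks the first
    row of each distinct-time segment.
    """
    n, p = Xs.shape
    eta = Xs @ beta
    shift = eta.max() if n else 0.0
    w = np.exp(eta - shift)
    seg_w = np.add.reduceat(w, first)
    S0 = np.cumsum(seg_w[::-1])[::-1]
    wx = w[:, None] * Xs
    S1 = np.cumsum(np.add.reduceat(wx, first, axis=0)[::-1], axis=0)[::-1]

    evf = ev.astype(float)
    d_all = np.add.reduceat(evf, first).astype(int)
    has_ev = d_all > 0
    De0 = np.add.reduceat(w * evf, first)
    De1 = np.add.reduceat(wx * evf[:, None], first, axis=0)
    sum_x_ev = np.add.reduceat(Xs * evf[:, None], first, axis=0)

    g_idx = np.flatnonzero(has_ev)
    g_rep_local, a = _pseudo_terms(d_all[g_idx], ties)
    g_rep = g_idx[g_rep_local]

    s0 = S0[g_rep] - a * De0[g_rep]
    s1 = S1[g_rep] - a[:, None] * De1[g_rep]
    xbar = s1 / s0[:, None]

    # log(S0) on the original scale is log(s0) + shift, once per pseudo term.
    loglik = float((eta * evf).sum() - (np.log(s0) + shift).sum())
    grad = sum_x_ev.sum(axis=0) - xbar.sum(axis=0)

    hess = None
    if need_hessian:
        wxx = wx[:, :, None] * Xs[:, None, :]
        S2 = np.cumsum(np.add.reduceat(wxx, first, axis=0)[::-1], axis=0)[::-1]
        De2 = np.add.reduceat(wxx * evf[:, None, None], first, axis=0)
        s2 = S2[g_rep] - a[:, None, None] * De2[g_rep]
        hess = (s2 / s0[:, None, None]).sum(axis=0) - np.einsum(
            "tp,tq->pq", xbar, xbar)
    cache = {"w": w, "s0": s0, "xbar": xbar, "a": a, "g_rep": g_rep,
             "first": first, "d_all": d_all, "evf": evf}
    return loglik, grad, hess, cache


def _drop_redundant_design(X: pd.DataFrame):
    dropped = []
    keep = []
    seen = {}
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if v.std() == 0:
            dropped.append(col)
            continue
        key = v.tobytes()
        if key in seen:
            dropped.append(col)
            continue
        seen[key] = col
        keep.append(col)
    return X[keep], dropped


def fit_cox(design, times, events, ties: str = "efron", cluster=None,
            max_iter: int = 100, tol: float = 1e-8) -> SurvivalFit:
    """Cox proportional-hazards fit.

    ``design`` is a DataFrame (column names kept) or array.  If
    ``cluster`` ids are given, a cluster-robust sandwich covariance is
    attached.  Raises :class:`ConvergenceError` on non-convergence and
    names the covariate when the likelihood is monotone (infinite
    coefficient).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    if isinstance(design, pd.DataFrame):
        design, dropped = _drop_redundant_design(design)
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() == 0:
        raise ValueError("no events: partial likelihood is undefined")
    if np.any(t < 0):
        raise ValueError("survival times must be >= 0")

    order = np.argsort(t, kind="stable")
    Xs, ts, ev = X[order], t[order], e[order]
    first = np.flatnonzero(np.r_[True, ts[1:] != ts[:-1]])

    col_scale = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)

    def check_monotone(beta):
        # log-hazard per covariate SD beyond any plausible effect size
        scaled = np.abs(beta) * col_scale
        if np.max(scaled) > 15:
            worst = names[int(np.argmax(scaled))]
            raise ConvergenceError(
                f"monotone likelihood: coefficient for {worst!r} diverges")

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess, cache = _cox_pass(Xs, ev, first, beta, ties)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular information matrix; design may be collinear") from exc
        # Step-halving on likelihood decrease.
        for _ in range(30):
            cand = beta + step
            ll_new, grad_new, hess_new, cache_new = _cox_pass(Xs, ev, first, cand, ties)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll, grad, hess, cache = cand, ll_new, grad_new, hess_new, cache_new
        check_monotone(beta)
    else:
        raise ConvergenceError(f"Newton-Raphson failed to converge in {max_iter} iterations")

    cov = np.linalg.inv(hess)
    resid = _score_residuals(Xs, ev, first, cache)
    # Undo the time sort so residual rows align with the input order.
    resid_unsorted = np.empty_like(resid)
    resid_unsorted[order] = resid
    fit = SurvivalFit(names=names, coef=beta, cov=cov, robust_cov=None,
                      n=len(t), n_events=int(e.sum()), ties=ties, loglik=ll,
                      n_iter=n_iter, score_residuals=resid_unsorted)
    if cluster is not None:
        fit.robust_cov = robust_cluster_variance(fit, cluster)
    return fit


def _score_residuals(Xs, ev, first, cache):
    """Per-subject score residuals (Efron-weighted); rows sum to the gradient."""
    w = cache["w"]
    s0 = cache["s0"]
    xbar = cache["xbar"]
    a = cache["a"]
    g_rep = cache["g_rep"]
    d_all = cache["d_all"]
    evf = cache["evf"]
    n, p = Xs.shape
    G = len(first)

    inv_s0 = 1.0 / s0
    # Per-segment aggregates of the pseudo terms.
    c0 = np.zeros(G)
    np.add.at(c0, g_rep, inv_s0)
    c1 = np.zeros((G, p))
    np.add.at(c1, g_rep, xbar * inv_s0[:, None])
    a0 = np.zeros(G)
    np.add.at(a0, g_rep, a * inv_s0)
    a1 = np.zeros((G, p))
    np.add.at(a1, g_rep, (a * inv_s0)[:, None] * xbar)
    xbar_mean = np.zeros((G, p))
    np.add.at(xbar_mean, g_rep, xbar)
    with np.errstate(invalid="ignore"):
        xbar_mean = np.where(d_all[:, None] > 0, xbar_mean / np.maximum(d_all, 1)[:, None], 0.0)

    C0 = np.cumsum(c0)
    C1 = np.cumsum(c1, axis=0)
    seg_id = np.searchsorted(first, np.arange(len(Xs)), side="right") - 1

    U = -w[:, None] * (Xs * C0[seg_id][:, None] - C1[seg_id])
    is_ev = evf.astype(bool)
    g_ev = seg_id[is_ev]
    U[is_ev] += Xs[is_ev] - xbar_mean[g_ev]
    U[is_ev] += w[is_ev, None] * (Xs[is_ev] * a0[g_ev][:, None] - a1[g_ev])
    return U


def robust_cluster_variance(fit: SurvivalFit, cluster) -> np.ndarray:
    """Sandwich covariance with score residuals summed within clusters."""
    if fit.score_residuals is None:
        raise ValueError("fit carries no score residuals")
    cluster = np.asarray(cluster)
    if len(cluster) != fit.n:
        raise ValueError("cluster id length does not match number of subjects")
    _, inv = np.unique(cluster, return_inverse=True)
    p = len(fit.coef)
    M = np.zeros((inv.max() + 1, p))
    np.add.at(M, inv, fit.score_residuals)
    B = M.T @ M
    V = fit.cov @ B @ fit.cov
    return (V + V.T) / 2.0


def hazard_ratio_ci(fit: SurvivalFit, level: float = 0.95):
    """(HR, lower, upper) per coefficient via the log-scale normal CI."""
    z = norm.ppf(0.5 + level / 2.0)
    se = fit.se
    hr = np.exp(fit.coef)
    lo = np.exp(fit.coef - z * se)
    hi = np.exp(fit.coef + z * se)
    return hr, lo, hi


def node_ratio(nodes_positive, nodes_removed):
    """Positive-to-removed lymph-node ratio, in [0, 1]."""
    pos = np.asarray(nodes_positive, dtype=float)
    rem = np.asarray(nodes_removed, dtype=float)
    if np.any(rem < 1):
        raise ValueError("nodes_removed must be >= 1 (records without axillary "
                         "surgery are excluded)")
    return pos / rem


def median_follow_up(times, events=None, method: str = "observed") -> float:
    """Median follow-up in months.

    ``observed`` is the median time to event or censoring; ``reverse_km``
    is the Kaplan-Meier median of the censoring distribution.
    """
    t = np.asarray(times, dtype=float)
    if method == "observed":
        return float(np.median(t))
    if method != "reverse_km":
        raise ValueError(f"unknown method {method!r}")
    if events is None:
        raise ValueError("reverse_km requires event indicators")
    e = 1 - np.asarray(events, dtype=int)
    curve = kaplan_meier(t, e)
    below = curve.survival <= 0.5
    if not below.any():
        return float("nan")
    return float(curve.times[np.argmax(below)])
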