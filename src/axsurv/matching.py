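"""Propensity-score estimation and 1:1 caliper matching with balance checks."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "PerfectSeparationError", "PropensityFit", "MatchedCohort",
    "encode_covariates", "fit_propensity", "match_nearest",
    "standardized_mean_difference", "balance_report",
]

DEFAULT_COVARIATES = [
    "age_group", "year_dx", "histology", "grade", "er", "pr", "her2",
    "t_category", "n_category", "systemic", "bcs", "radiotherapy",
]


class PerfectSeparationError(RuntimeError):
    """Logistic model separates the groups; the offending column is named."""


@dataclasses.dataclass
class PropensityFit:
    coefficients: pd.Series
    scores: np.ndarray
    converged: bool
    n_iter: int
    covariates: list[str]
    dropped: list[str]
    loglik: float
    cov: np.ndarray | None = None    # inverse Fisher information

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)),
                         index=self.coefficients.index)


@dataclasses.dataclass
class MatchedCohort:
    pairs: pd.DataFrame          # columns: pair_id, treated_id, control_id
    caliper: float
    caliper_multiplier: float
    n_treated: int
    n_unmatched_treated: int
    logit_scores: pd.Series      # indexed by record id

    @property
    def matched_ids(self) -> np.ndarray:
        return np.concatenate([self.pairs["treated_id"].to_numpy(),
                               self.pairs["control_id"].to_numpy()])


def encode_covariates(records: pd.DataFrame, covariates) -> pd.DataFrame:
    """Dummy-encode categorical covariates (first level dropped)."""
    pieces = []
    for cov in covariates:
        col = records[cov]
        if col.dtype == object or str(col.dtype) == "category":
            d = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            pieces.append(d)
        else:
            nuniq = col.nunique(dropna=True)
            if nuniq > 2 or set(col.dropna().unique()) <= {0, 1}:
                pieces.append(col.astype(float).rename(cov))
            else:
                pieces.append(pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float))
    return pd.concat(pieces, axis=1)


def _drop_redundant(X: pd.DataFrame):
    """Drop constant and duplicated columns, returning (X, dropped names)."""
    dropped = []
    keep = []
    seen = {}
    for col in X.columns:
        v = X[col].to_numpy()
        if np.nanstd(v) == 0:
            dropped.append(col)
            continue
        key = v.tobytes()
        if key in seen:
            dropped.append(col)
            continue
        seen[key] = col
        keep.append(col)
    return X[keep], dropped


def fit_propensity(records: pd.DataFrame, covariates=None,
                   treatment_col: str = "final_label",
                   treated_value: str = "ALND",
                   max_iter: int = 100, tol: float = 1e-8) -> PropensityFit:
    """Logistic propensity model fitted by IRLS.

    Convergence at relative log-likelihood change < ``tol``; constant
    and duplicated encoded columns are dropped before fitting.  Raises
    :class:`PerfectSeparationError` when a covariate separates the
    groups.
    """
    covariates = list(covariates or DEFAULT_COVARIATES)
    y = (records[treatment_col] == treated_value).to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both exposure groups must be present")
    Xdf = encode_covariates(records, covariates)
    Xdf, dropped = _drop_redundant(Xdf)
    names = ["intercept"] + list(Xdf.columns)
    Xraw = Xdf.to_numpy(dtype=float)
    # Standardise internally for conditioning; coefficients are mapped
    # back to the original scale afterwards.
    mu = Xraw.mean(axis=0)
    sd = Xraw.std(axis=0)
    X = np.column_stack([np.ones(len(records)), (Xraw - mu) / sd])

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = float(y @ np.log(p) + (1 - y) @ np.log(1 - p))
        if np.isfinite(ll_old) and abs(ll - ll_old) < tol * (abs(ll_old) + 1e-12):
            converged = True
            break
        ll_old = ll
        w = p * (1 - p)
        H = X.T @ (X * w[:, None])
        g = X.T @ (y - p)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(len(beta)), g)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise PerfectSeparationError(str(exc)) from exc
        beta = beta + step
        if X.shape[1] > 1 and np.max(np.abs(beta[1:])) > 15:
            worst = names[1:][int(np.argmax(np.abs(beta[1:])))]
            raise PerfectSeparationError(
                f"perfect separation suspected; covariate {worst!r} diverges")
    scores = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    coef = np.empty_like(beta)
    coef[1:] = beta[1:] / sd
    coef[0] = beta[0] - np.sum(beta[1:] * mu / sd)
    # Fisher information on the original scale.
    Xo = np.column_stack([np.ones(len(records)), Xraw])
    w = scores * (1 - scores)
    cov = np.linalg.inv(Xo.T @ (Xo * w[:, None]))
    return PropensityFit(coefficients=pd.Series(coef, index=names),
                         scores=scores, converged=converged, n_iter=it,
                         covariates=covariates, dropped=dropped, loglik=ll_old,
                         cov=cov)


def match_nearest(scores, exposure, ids=None, caliper_multiplier: float = 0.2,
                  sd_scope: str = "pooled") -> MatchedCohort:
    """Greedy 1:1 nearest-neighbour matching on the logit score.

    Caliper = ``caliper_multiplier`` x SD of the logit scores (pooled
    sample by default, ``sd_scope="treated"`` to use treated only).
    Treated subjects are processed in descending score order; each is
    paired with the nearest unmatched control within the caliper
    (distance on the logit scale, ties broken by lowest record id);
    controls are never reused.
    """
    scores = np.asarray(scores, dtype=float)
    exp_arr = np.asarray(exposure)
    treated = exp_arr if exp_arr.dtype == bool else np.isin(exp_arr, [1, True, "ALND"])
    if ids is None:
        ids = np.arange(len(scores))
    ids = np.asarray(ids)
    lg = logit(np.clip(scores, 1e-12, 1 - 1e-12))

    if not (~treated).any():
        raise ValueError("no control subjects available")
    sd_pool = lg[treated] if sd_scope == "treated" else lg
    caliper = caliper_multiplier * float(np.std(sd_pool, ddof=1))

    t_idx = np.flatnonzero(treated)
    c_idx = np.flatnonzero(~treated)
    # Deterministic orders: treated by descending score then id;
    # controls sorted by (logit, id) for the neighbour scan.
    t_order = t_idx[np.lexsort((ids[t_idx], -scores[t_idx]))]
    c_order = c_idx[np.lexsort((ids[c_idx], lg[c_idx]))]
    clg = lg[c_order]
    cids = ids[c_order]
    nc = len(c_order)
    alive = np.ones(nc, dtype=bool)
    # Jump pointers to the nearest possibly-alive slot in each direction,
    # path-compressed as controls are consumed.
    right_ptr = list(range(nc + 1))
    left_ptr = list(range(nc))

    def find_right(j):
        path = []
        while j < nc and not alive[j]:
            path.append(j)
            j = right_ptr[j]
        for q in path:
            right_ptr[q] = j
        return j

    def find_left(j):
        path = []
        while j >= 0 and not alive[j]:
            path.append(j)
            j = left_ptr[j]
        for q in path:
            left_ptr[q] = j
        return j

    pairs = []
    n_unmatched = 0
    for ti in t_order:
        x = lg[ti]
        pos = int(np.searchsorted(clg, x))
        best = -1
        best_dist = np.inf
        j = find_right(pos)
        if j < nc:
            best, best_dist = j, abs(clg[j] - x)
        j = find_left(pos - 1)
        if j >= 0:
            d = abs(clg[j] - x)
            if d < best_dist or (d == best_dist and best >= 0 and cids[j] < cids[best]):
                best, best_dist = j, d
        if best >= 0 and best_dist <= caliper:
            pairs.append((ids[ti], cids[best]))
            alive[best] = False
            right_ptr[best] = best + 1
            left_ptr[best] = best - 1
        else:
            n_unmatched += 1

    pair_df = pd.DataFrame(pairs, columns=["treated_id", "control_id"])
    pair_df.insert(0, "pair_id", np.arange(len(pair_df)))
    return MatchedCohort(pairs=pair_df, caliper=caliper,
                         caliper_multiplier=caliper_multiplier,
                         n_treated=len(t_order), n_unmatched_treated=n_unmatched,
                         logit_scores=pd.Series(lg, index=ids))


def standardized_mean_difference(values_treated, values_control, kind: str = "continuous"):
    """Absolute standardised mean difference between two groups.

    ``kind`` is "continuous" (pooled-variance denominator) or "binary"
    (proportion-based denominator).  Returns 0 when both numerator and
    denominator vanish.
    """
    vt = np.asarray(values_treated, dtype=float)
    vc = np.asarray(values_control, dtype=float)
    if vt.size == 0 or vc.size == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "binary":
        pt, pc = vt.mean(), vc.mean()
        num = abs(pt - pc)
        denom = np.sqrt((pt * (1 - pt) + pc * (1 - pc)) / 2.0)
    elif kind == "continuous":
        num = abs(vt.mean() - vc.mean())
        denom = np.sqrt((vt.var(ddof=1) + vc.var(ddof=1)) / 2.0) \
            if vt.size > 1 or vc.size > 1 else 0.0
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if num == 0 and (denom == 0 or np.isnan(denom)):
        return 0.0
    return float(num / denom)


def _smd_kind(col: np.ndarray) -> str:
    uniq = np.unique(col[~np.isnan(col)])
    return "binary" if set(uniq) <= {0.0, 1.0} else "continuous"


def balance_report(matched: MatchedCohort, records: pd.DataFrame,
                   covariates=None, treatment_col: str = "final_label",
                   treated_value: str = "ALND", threshold: float = 0.1,
                   id_col: str = "id"):
    """Pre/post-match SMD per encoded covariate plus a pass flag.

    Returns a dict with the long-format balance table, the list of
    covariates failing the post-match threshold, the common-support
    summary of the logit scores, and ``passed``.
    """
    if len(matched.pairs) == 0:
        raise ValueError("matched cohort is empty")
    covariates = list(covariates or DEFAULT_COVARIATES)
    X = encode_covariates(records, covariates)
    treated = (records[treatment_col] == treated_value).to_numpy()
    rid = records[id_col].to_numpy()
    in_matched = np.isin(rid, matched.matched_ids)

    rows = []
    failing = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        kind = _smd_kind(v)
        pre = standardized_mean_difference(v[treated], v[~treated], kind)
        post = standardized_mean_difference(v[treated & in_matched],
                                            v[~treated & in_matched], kind)
        rows.append({"covariate": col, "stage": "pre", "smd": pre})
        rows.append({"covariate": col, "stage": "post", "smd": post})
        if post > threshold:
            failing.append(col)
    table = pd.DataFrame(rows)

    lg = matched.logit_scores
    lg_t = lg.loc[rid[treated]].to_numpy()
    lg_c = lg.loc[rid[~treated]].to_numpy()
    support = {
        "treated_range": (float(lg_t.min()), float(lg_t.max())),
        "control_range": (float(lg_c.min()), float(lg_c.max())),
        "overlap": (float(max(lg_t.min(), lg_c.min())),
                    float(min(lg_t.max(), lg_c.max()))),
    }
    return {"table": table, "failing": failing, "passed": not failing,
            "threshold": threshold, "common_support": support}
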