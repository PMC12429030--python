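"""Chained-equations multiple imputation with predictive mean matching.

A single PMM engine serves continuous, binary, ordinal and categorical
variables: each variable with missing values is regressed (on a numeric
working encoding) on all other variables, and each missing cell receives
the observed value of one of the k donors whose predicted means are
closest to the target's predicted mean.  Imputed values are therefore
always observed values of the same variable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ImputationSet", "mice_pmm", "pmm_draw", "rubin_pool"]


@dataclasses.dataclass
class ImputationSet:
    """m completed copies of a record table plus the missingness mask."""

    datasets: list[pd.DataFrame]
    mask: pd.DataFrame
    m: int
    max_iter: int
    k_donors: int
    seed: int | None

    def export(self, out_dir: str | Path, stem: str = "imputed") -> None:
        """Write the m tables as CSV plus a JSON manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.datasets, start=1):
            df.to_csv(out_dir / f"{stem}_{i}.csv", index=False)
        manifest = {"m": self.m, "max_iter": self.max_iter,
                    "k_donors": self.k_donors, "seed": self.seed,
                    "files": [f"{stem}_{i}.csv" for i in range(1, self.m + 1)]}
        (out_dir / f"{stem}_manifest.json").write_text(json.dumps(manifest, indent=2))


def pmm_draw(target_pred: float, donor_preds, donor_values, k: int, rng=None):
    """Predictive-mean-matching draw for a single target.

    Returns the observed value of one of the ``k`` donors whose
    predictions are closest to ``target_pred`` (uniform choice among
    them).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    donor_preds = np.asarray(donor_preds, dtype=float)
    donor_values = np.asarray(donor_values)
    if donor_preds.size == 0:
        raise ValueError("at least one donor is required")
    if rng is None:
        rng = np.random.default_rng()
    k_eff = min(k, donor_preds.size)
    order = np.argsort(np.abs(donor_preds - target_pred), kind="stable")
    pick = order[rng.integers(k_eff)]
    return donor_values[pick]


def _pmm_match_many(target_preds, donor_preds, donor_values, k, rng):
    """Vectorised PMM: nearest-k donor search via a sorted window."""
    order = np.argsort(donor_preds, kind="stable")
    dp = donor_preds[order]
    dv = donor_values[order]
    nd = dp.size
    k_eff = min(k, nd)
    window = min(2 * k_eff, nd)
    pos = np.searchsorted(dp, target_preds)
    start = np.clip(pos - k_eff, 0, nd - window)
    cand = start[:, None] + np.arange(window)[None, :]
    dist = np.abs(dp[cand] - target_preds[:, None])
    nearest = np.argpartition(dist, k_eff - 1, axis=1)[:, :k_eff]
    pick = nearest[np.arange(len(target_preds)), rng.integers(k_eff, size=len(target_preds))]
    return dv[cand[np.arange(len(target_preds)), pick]]


def _encode(df: pd.DataFrame):
    """Numeric working copy; object columns become category codes."""
    work = pd.DataFrame(index=df.index)
    decoders = {}
    for col in df.columns:
        if df[col].dtype == object:
            cat = pd.Categorical(df[col])
            codes = np.asarray(cat.codes, dtype=float)
            codes[codes < 0] = np.nan
            work[col] = codes
            decoders[col] = np.asarray(cat.categories)
        else:
            work[col] = df[col].astype(float)
    return work, decoders


def mice_pmm(records: pd.DataFrame, mask: pd.DataFrame | None = None,
             m: int = 5, max_iter: int = 10, k_donors: int = 5,
             seed: int | None = None) -> ImputationSet:
    """Multiple imputation by chained equations with PMM.

    Variables are swept in ascending order of missingness fraction for
    ``max_iter`` cycles.  Observed cells are never altered.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if mask is None:
        mask = records.isna()
    if mask.shape != records.shape or list(mask.columns) != list(records.columns):
        raise ValueError("mask and record table shapes/columns must match")
    mask = mask.astype(bool)

    miss_frac = mask.mean(axis=0)
    targets = [c for c in records.columns if miss_frac[c] > 0]
    for col in targets:
        if miss_frac[col] >= 1.0:
            raise ValueError(f"variable {col!r} is fully missing; cannot impute")
    sweep = sorted(targets, key=lambda c: (miss_frac[c], records.columns.get_loc(c)))

    rng = np.random.default_rng(seed)
    work0, decoders = _encode(records)
    # Null out any masked cells that still carry values.
    for col in targets:
        work0.loc[mask[col].to_numpy(), col] = np.nan

    predictors = {c: [o for o in records.columns if o != c] for c in sweep}
    datasets = []
    for _ in range(m):
        work = work0.copy()
        # Initial fill: random draws from the observed values.
        for col in sweep:
            hit = mask[col].to_numpy()
            obs = work.loc[~hit, col].to_numpy()
            work.loc[hit, col] = rng.choice(obs, size=int(hit.sum()), replace=True)
        for _ in range(max_iter):
            for col in sweep:
                hit = mask[col].to_numpy()
                X = work[predictors[col]].to_numpy()
                X = np.column_stack([np.ones(len(X)), X])
                y = work[col].to_numpy()
                Xo, yo = X[~hit], y[~hit]
                # Ridge-stabilised normal equations.
                A = Xo.T @ Xo + 1e-8 * np.eye(X.shape[1])
                b = Xo.T @ yo
                beta_hat = np.linalg.solve(A, b)
                resid = yo - Xo @ beta_hat
                dof = max(len(yo) - X.shape[1], 1)
                sigma2 = float(resid @ resid) / dof
                # Parameter draw so the m chains differ (proper MI).
                cov = sigma2 * np.linalg.inv(A)
                beta_star = rng.multivariate_normal(beta_hat, cov, method="cholesky")
                donor_preds = Xo @ beta_star
                target_preds = X[hit] @ beta_star
                work.loc[hit, col] = _pmm_match_many(
                    target_preds, donor_preds, yo, k_donors, rng)
        datasets.append(_decode(work, records, decoders, mask))
    return ImputationSet(datasets=datasets, mask=mask, m=m,
                         max_iter=max_iter, k_donors=k_donors, seed=seed)


def _decode(work: pd.DataFrame, original: pd.DataFrame, decoders, mask) -> pd.DataFrame:
    out = original.copy()
    for col in original.columns:
        hit = mask[col].to_numpy()
        if not hit.any():
            continue
        vals = work.loc[hit, col].to_numpy()
        if col in decoders:
            out[col] = out[col].astype(object)
            out.loc[hit, col] = decoders[col][vals.astype(int)]
        else:
            if out[col].dtype.kind in "iu":
                out[col] = out[col].astype(float)
            out.loc[hit, col] = vals
    return out


def rubin_pool(estimates, variances):
    """Combine per-imputation estimates and variances.

    pooled = mean of estimates; total variance = mean within-variance
    + (1 + 1/m) * between-imputation variance.  Works elementwise for
    vector-valued estimates.
    """
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if estimates.shape != variances.shape:
        raise ValueError("estimates and variances must have equal shape")
    m = estimates.shape[0]
    if m < 1:
        raise ValueError("need at least one imputation")
    pooled = estimates.mean(axis=0)
    within = variances.mean(axis=0)
    if m == 1:
        return pooled, within
    between = estimates.var(axis=0, ddof=1)
    total = within + (1.0 + 1.0 / m) * between
    return pooled, total
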