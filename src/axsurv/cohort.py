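"""Synthetic registry-style breast-cancer cohort generation.

Generates patient-level tables with a known latent axillary procedure
(SLNB vs ALND), node counts on procedure-specific supports, a
proportional-hazards cause-specific survival mechanism with
right-censoring, and configurable per-field missingness.  Every
downstream stage of the pipeline can therefore be tested against ground
truth without access to any restricted registry.
"""

from __future__ import annotations

import copy
import dataclasses
import importlib.resources
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import truncnorm

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "PN_BOUNDS",
    "PROTECTED_FIELDS",
    "derive_pn_category",
    "generate_cohort",
    "draw_node_counts",
    "draw_survival_outcome",
    "inject_missingness",
    "hazard_features",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


#: pN category -> (min, max) positive-node count under the count-based
#: convention pN0=0, pN1=1-3, pN2=4-9, pN3>=10.
PN_BOUNDS = {0: (0, 0), 1: (1, 3), 2: (4, 9), 3: (10, np.inf)}

#: Fields that define exposure/outcome and must never be masked.
PROTECTED_FIELDS = frozenset(
    {"nodes_removed", "nodes_positive", "n_category", "surv_months", "event"}
)

AGE_LEVELS = ["<50", "50-74", ">=75"]
HISTOLOGY_LEVELS = ["ductal", "lobular", "mixed", "other"]

_COLUMNS = [
    "id", "age_group", "year_dx", "t_category", "n_category", "histology",
    "grade", "er", "pr", "her2", "bcs", "systemic", "radiotherapy",
    "months_dx_to_tx", "nodes_removed", "nodes_positive", "latent_procedure",
    "surv_months", "event", "metastatic_flag", "tis_flag",
    "neoadjuvant_flag", "nonepithelial_flag",
]


def derive_pn_category(nodes_positive: np.ndarray) -> np.ndarray:
    """Map positive-node counts onto pN categories 0-3."""
    pos = np.asarray(nodes_positive)
    return np.select([pos == 0, pos <= 3, pos <= 9], [0, 1, 2], default=3)


def _deep_merge(base: dict, update: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in update.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val) if isinstance(val, (dict, list)) else val
    return out


@dataclasses.dataclass
class SimulationConfig:
    """Container for all cohort-simulation parameters.

    Use :meth:`default` for the versioned defaults shipped with the
    package and :meth:`from_dict` to apply overrides on top of them.
    """

    params: dict[str, Any]

    def __getattr__(self, name: str) -> Any:
        try:
            return self.params[name]
        except KeyError as exc:  # pragma: no cover - attribute plumbing
            raise AttributeError(name) from exc

    def __getitem__(self, name: str) -> Any:
        return self.params[name]

    @classmethod
    def default(cls) -> "SimulationConfig":
        text = (
            importlib.resources.files("axsurv.data")
            .joinpath("default_cohort.yaml")
            .read_text()
        )
        return cls(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, overrides: Mapping | None = None) -> "SimulationConfig":
        base = cls.default().params
        return cls(_deep_merge(base, overrides or {}))

    def validate(self) -> None:
        for key in ("age_probs", "t_probs", "n_probs", "histology_probs", "grade_probs"):
            probs = np.array(list(self.params[key].values()), dtype=float)
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"{key} must be non-negative and sum to 1 (got sum {probs.sum()})"
                )
        for key in ("p_er", "p_pr", "p_her2", "p_bcs", "p_systemic", "p_radiotherapy"):
            p = self.params[key]
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{key}={p} outside [0, 1]")
        if self.params["baseline_hazard"] <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        for name, spec in (("slnb_nodes", (1, 5)), ("alnd_nodes", (4, 82))):
            lo, hi = self.params[name]["low"], self.params[name]["high"]
            if lo < spec[0] or hi > spec[1] or lo > hi:
                raise ConfigurationError(
                    f"{name} support [{lo}, {hi}] outside allowed range {spec}"
                )
        for field, mspec in self.params.get("missingness", {}).items():
            if not 0.0 <= mspec["rate"] <= 1.0:
                raise ConfigurationError(f"missingness rate for {field} outside [0, 1]")


def _draw_categorical(rng, probs_map, n):
    keys = list(probs_map)
    probs = np.array([probs_map[k] for k in keys], dtype=float)
    idx = rng.choice(len(keys), size=n, p=probs / probs.sum())
    return np.array(keys, dtype=object)[idx]


def _calibrated_loc(mean, sd, lo, hi):
    """Location making the [lo, hi]-truncated normal mean equal ``mean``."""
    from scipy.optimize import brentq

    def gap(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    margin = 0.02 * (hi - lo)
    if not lo + margin < mean < hi - margin:
        return mean
    try:
        return brentq(gap, lo - 8 * sd, hi + 8 * sd, xtol=1e-6)
    except ValueError:  # pragma: no cover - target outside attainable range
        return mean


def _discrete_truncnorm(rng, mean, sd, low, high, n):
    # Continuity-corrected truncation so rounded draws stay on [low, high];
    # the location is solved so the truncated mean matches the target.
    lo_c, hi_c = low - 0.5, high + 0.5
    loc = _calibrated_loc(mean, sd, lo_c, hi_c)
    a = (lo_c - loc) / sd
    b = (hi_c - loc) / sd
    x = truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(x).astype(int), low, high)


def _truncated_geometric(rng, span, decay, n):
    """Draw j in [0, span] with P(j) proportional to decay**j, elementwise."""
    span = np.asarray(span, dtype=float)
    u = rng.random(n)
    total = 1.0 - decay ** (span + 1.0)
    j = np.floor(np.log1p(-u * total) / np.log(decay))
    return np.minimum(j, span).astype(int)


def draw_node_counts(procedure, n_category, config: SimulationConfig, rng):
    """Draw (nodes_removed, nodes_positive) consistent with the pN category.

    SLNB counts lie on [1, 5]; ALND counts on [4, 82] (lifted further when
    the pN category requires more positive nodes than the raw draw allows).
    """
    procedure = np.atleast_1d(np.asarray(procedure, dtype=object))
    n_category = np.atleast_1d(np.asarray(n_category, dtype=int))
    if procedure.shape != n_category.shape:
        raise ValueError("procedure and n_category must have equal length")
    n = len(procedure)
    is_alnd = procedure == "ALND"
    if np.any(~is_alnd & (n_category >= 2)):
        raise ValueError("SLNB is incompatible with pN2/pN3 (needs >=4 positive nodes)")

    removed = np.empty(n, dtype=int)
    for mask, spec in ((~is_alnd, config.slnb_nodes), (is_alnd, config.alnd_nodes)):
        k = int(mask.sum())
        if k:
            removed[mask] = _discrete_truncnorm(
                rng, spec["mean"], spec["sd"], spec["low"], spec["high"], k
            )

    lo = np.array([PN_BOUNDS[c][0] for c in n_category])
    hi = np.array([min(PN_BOUNDS[c][1], 82) for c in n_category])
    removed = np.maximum(removed, lo)  # pN3 forces >=10 removed
    hi_eff = np.minimum(hi, removed)
    span = hi_eff - lo
    positive = lo + _truncated_geometric(rng, span, config.positive_decay, n)
    return removed, positive


def hazard_features(df: pd.DataFrame, treatment_col: str = "latent_procedure") -> pd.DataFrame:
    """Numeric feature table used by the log-hazard linear predictor.

    The same encoding is used by the simulator and by the adjusted Cox
    models downstream, so that planted coefficients are recoverable.
    """
    out = pd.DataFrame(index=df.index)
    out["age_lt50"] = (df["age_group"] == "<50").astype(float)
    out["age_ge75"] = (df["age_group"] == ">=75").astype(float)
    out["year_c"] = df["year_dx"].astype(float) - 2010.0
    out["t2"] = (df["t_category"] == 2).astype(float)
    out["grade2"] = (df["grade"] == 2).astype(float)
    out["grade3"] = (df["grade"] == 3).astype(float)
    out["hist_lobular"] = (df["histology"] == "lobular").astype(float)
    out["hist_mixed"] = (df["histology"] == "mixed").astype(float)
    out["hist_other"] = (df["histology"] == "other").astype(float)
    for col in ("er", "pr", "her2", "bcs", "systemic", "radiotherapy"):
        out[col] = df[col].astype(float)
    out["tx_delay"] = df["months_dx_to_tx"].astype(float)
    for k in (1, 2, 3):
        out[f"n{k}"] = (df["n_category"] == k).astype(float)
    out["nodes_positive"] = df["nodes_positive"].astype(float)
    out["nodes_removed"] = df["nodes_removed"].astype(float)
    removed = df["nodes_removed"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(removed > 0, df["nodes_positive"].to_numpy(dtype=float) / removed, 0.0)
    out["node_ratio"] = ratio
    if treatment_col in df:
        out["alnd"] = (df[treatment_col] == "ALND").astype(float)
    else:
        out["alnd"] = 0.0
    return out


def _linear_predictor(df: pd.DataFrame, coeffs: Mapping[str, float],
                      treatment_col: str = "latent_procedure") -> np.ndarray:
    feats = hazard_features(df, treatment_col=treatment_col)
    lp = np.zeros(len(df))
    for name, coef in coeffs.items():
        if name not in feats:
            raise ConfigurationError(f"unknown log-hazard feature: {name!r}")
        if coef:
            lp += coef * feats[name].to_numpy()
    return lp


def draw_survival_outcome(df: pd.DataFrame, config: SimulationConfig, rng):
    """Draw (surv_months, event) from the exponential PH mechanism.

    Event times are exponential with hazard ``baseline * exp(lp)``;
    censoring is the minimum of the administrative horizon and an
    optional random (loss-to-follow-up) exponential time.
    """
    lp = _linear_predictor(df, config.log_hazard)
    rate = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    horizon = float(config.horizon_months)
    c = np.full(len(df), horizon)
    # Staggered entry: follow-up runs out at the study end year.
    end_year = config.params.get("study_end_year")
    if end_year is not None:
        admin = np.clip((float(end_year) - df["year_dx"].to_numpy(dtype=float)) * 12.0,
                        0.0, horizon)
        c = np.minimum(c, admin)
    if config.censoring_rate and config.censoring_rate > 0:
        c = np.minimum(c, rng.exponential(1.0 / config.censoring_rate, size=len(df)))
    event = (t_event <= c).astype(int)
    surv = np.minimum(t_event, c)
    if config.params.get("round_months", False):
        surv = np.rint(surv)
    return surv, event


def generate_cohort(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate ``config.n`` patient records with full latent ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(config.n)
    if n == 0:
        return pd.DataFrame(columns=_COLUMNS)

    df = pd.DataFrame({"id": np.arange(n)})
    df["age_group"] = _draw_categorical(rng, config.age_probs, n)
    lo, hi = config.year_range
    df["year_dx"] = _discrete_truncnorm(rng, config.year_mean, config.year_sd, lo, hi, n)
    df["t_category"] = _draw_categorical(rng, config.t_probs, n).astype(int)
    df["n_category"] = _draw_categorical(rng, config.n_probs, n).astype(int)
    df["histology"] = _draw_categorical(rng, config.histology_probs, n)
    df["grade"] = _draw_categorical(rng, config.grade_probs, n).astype(int)
    for col, p in (("er", config.p_er), ("pr", config.p_pr), ("her2", config.p_her2),
                   ("bcs", config.p_bcs), ("systemic", config.p_systemic),
                   ("radiotherapy", config.p_radiotherapy)):
        df[col] = (rng.random(n) < p).astype(int)
    mu, sd = config.tx_delay_mean, config.tx_delay_sd
    shape = (mu / sd) ** 2
    df["months_dx_to_tx"] = rng.gamma(shape, mu / shape, size=n)

    # Latent procedure: logistic in confounders, forced ALND for pN2/pN3.
    a = config.assignment
    lp = np.full(n, float(a.get("intercept", 0.0)))
    lp += a.get("year_c", 0.0) * (df["year_dx"].to_numpy() - 2010.0)
    lp += a.get("n1", 0.0) * (df["n_category"].to_numpy() == 1)
    lp += a.get("t2", 0.0) * (df["t_category"].to_numpy() == 2)
    lp += a.get("grade3", 0.0) * (df["grade"].to_numpy() == 3)
    lp += a.get("age_lt50", 0.0) * (df["age_group"].to_numpy() == "<50")
    lp += a.get("her2", 0.0) * df["her2"].to_numpy()
    p_alnd = expit(lp)
    p_alnd[df["n_category"].to_numpy() >= 2] = 1.0
    df["latent_procedure"] = np.where(rng.random(n) < p_alnd, "ALND", "SLNB")

    removed, positive = draw_node_counts(
        df["latent_procedure"].to_numpy(), df["n_category"].to_numpy(), config, rng
    )
    df["nodes_removed"] = removed
    df["nodes_positive"] = positive

    surv, event = draw_survival_outcome(df, config, rng)
    df["surv_months"] = surv
    df["event"] = event

    # Selection-test flags (all-zero under the defaults).
    rates = config.params.get("exclusion_rates", {})
    flags = {
        "tis_flag": "tis", "metastatic_flag": "m1",
        "neoadjuvant_flag": "neoadjuvant", "nonepithelial_flag": "nonepithelial",
    }
    for col, key in flags.items():
        df[col] = (rng.random(n) < rates.get(key, 0.0)).astype(int)
    if rates.get("t3t4", 0.0) > 0:
        df.loc[rng.random(n) < rates["t3t4"], "t_category"] = 3
    if rates.get("no_surgery", 0.0) > 0:
        hit = rng.random(n) < rates["no_surgery"]
        df.loc[hit, ["nodes_removed", "nodes_positive"]] = 0
    if rates.get("missing_core", 0.0) > 0:
        df.loc[rng.random(n) < rates["missing_core"], "surv_months"] = np.nan

    return df[_COLUMNS]


def inject_missingness(df: pd.DataFrame, config: SimulationConfig, rng=None):
    """Mask fields per the missingness spec; returns (masked table, mask).

    Exposure-defining fields (node counts, pN category, survival) are
    protected and may never be masked.  MAR missingness is logistic in
    age group and centred diagnosis year, with the intercept solved so
    the marginal rate matches the requested one.
    """
    from scipy.optimize import brentq

    if rng is None:
        rng = np.random.default_rng(config.seed)
    spec = config.params.get("missingness", {})
    out = df.copy()
    mask = pd.DataFrame(False, index=df.index, columns=df.columns)
    n = len(df)
    for field, fspec in spec.items():
        if field in PROTECTED_FIELDS:
            raise ConfigurationError(f"field {field!r} is protected and cannot be masked")
        if field not in df.columns:
            raise ConfigurationError(f"unknown field {field!r} in missingness spec")
        rate = float(fspec["rate"])
        mechanism = fspec.get("mechanism", "MCAR").upper()
        if rate <= 0 or n == 0:
            continue
        if rate >= 1.0:
            hit = np.ones(n, dtype=bool)
        elif mechanism == "MCAR":
            hit = rng.random(n) < rate
        elif mechanism == "MAR":
            age_idx = np.array([AGE_LEVELS.index(a) for a in df["age_group"]])
            lp = 0.6 * age_idx + 0.08 * (df["year_dx"].to_numpy() - 2010.0)
            offset = brentq(lambda b: expit(b + lp).mean() - rate, -40, 40)
            hit = rng.random(n) < expit(offset + lp)
        else:
            raise ConfigurationError(f"unknown missingness mechanism {mechanism!r}")
        mask[field] = hit
        if out[field].dtype.kind in "iu":
            out[field] = out[field].astype(float)
        out.loc[hit, field] = np.nan
    return out, mask
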