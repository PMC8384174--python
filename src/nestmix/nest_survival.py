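"""Daily nest-survival (DSR) exposure likelihood and tiered model selection.

Each monitored nest contributes an exposure likelihood built from its
known-alive interval and, for failed nests, the uncertainty window within
which failure occurred:

    l = (last_active - first_found) * log(s)
        + [failure] * log(1 - s^(last_checked - last_active))

with s the nest's daily survival rate, logit-linked to time-constant
covariates measured at the nest site and/or the plot scale.  Successful
nests contribute survival through last_active only.  The failure term is
exactly the sum over the latent failure day of a geometric sequence, so
enumeration and the closed form agree identically.

Model evaluation is tiered: a nest-site candidate set, a plot-scale set
(including within-plot SD covariates), then a multi-scale set combining
supported terms from both tiers.  Herbaceous biomass and exotic-grass
cover are too collinear to co-occur in one model and are kept in separate
candidate branches throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_hess2

from .data_model import EncounterRecord, encounter_records_to_frame
from .selection_gof import ModelSet

__all__ = [
    "DSRModel",
    "dsr",
    "nest_log_likelihood",
    "total_log_likelihood",
    "fit_dsr",
    "period_survival",
    "tiered_evaluation",
    "apparent_success",
]


@dataclass
class DSRModel:
    """A fitted daily-survival model."""

    beta: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    n_params: int
    effective_n: int                 # total exposure days
    term_names: list = field(default_factory=list)
    converged: bool = True
    warnings: list = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, np.inf))

    @property
    def dsr_intercept(self) -> float:
        """DSR at covariate means (all standardized covariates at zero)."""
        return float(special.expit(self.beta[0]))

    def dsr_intercept_se(self) -> float:
        s = self.dsr_intercept
        return float(s * (1 - s) * self.se()[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return special.expit(np.asarray(X) @ self.beta)

    def predict_var(self, X: np.ndarray) -> np.ndarray:
        """Delta-method variance of predicted DSR."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        s = self.predict(X)
        var_eta = np.einsum("ij,jk,ik->i", X, self.covariance, X)
        return (s * (1 - s)) ** 2 * np.clip(var_eta, 0, np.inf)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.beta, "se": self.se()},
                            index=self.term_names)


def dsr(covariates, beta) -> np.ndarray | float:
    """Daily survival probability: inverse-logit of the linear predictor."""
    x = np.asarray(covariates, dtype=float)
    b = np.asarray(beta, dtype=float)
    return special.expit(x @ b) if x.ndim else special.expit(x * b)


def nest_log_likelihood(record: EncounterRecord, s: float) -> float:
    """Exposure log-likelihood of one nest at daily survival ``s``."""
    expo = record.exposure_days
    ll = expo * np.log(s) if expo > 0 else 0.0
    if record.fate == "failure":
        window = record.failure_window
        if window <= 0:
            raise ValueError(
                f"nest {record.nest_id}: failure requires last_checked > last_active"
            )
        with np.errstate(divide="ignore"):
            ll += np.log1p(-s ** window) if s < 1 else -np.inf
    return float(ll)


def _design(records_df: pd.DataFrame, terms: list) -> tuple[np.ndarray, list]:
    n = len(records_df)
    cols, names = [np.ones(n)], ["(Intercept)"]
    for t in terms:
        if t == "year":
            years = sorted(records_df["year"].astype(str).unique())
            for y in years[1:]:  # two-level indicator, first year is the reference
                cols.append((records_df["year"].astype(str) == y).to_numpy(float))
                names.append(f"year[{y}]")
        else:
            if t not in records_df.columns:
                raise KeyError(f"covariate {t!r} not found in encounter records")
            cols.append(records_df[t].to_numpy(dtype=float))
            names.append(t)
    return np.column_stack(cols), names


def total_log_likelihood(exposure, window, failed, X, beta) -> float:
    """Vectorized sum of nest exposure log-likelihoods."""
    s = special.expit(X @ beta)
    ll = exposure * np.log(s)
    if failed.any():
        sw = s[failed] ** window[failed]
        with np.errstate(divide="ignore"):
            ll_fail = np.log1p(-sw)
        ll[failed] += ll_fail
    return float(ll.sum())


def fit_dsr(records: list[EncounterRecord] | pd.DataFrame,
            terms: list | None = None) -> DSRModel:
    """Maximum-likelihood fit of the logit-linked DSR model.

    ``terms`` name columns of the flattened record frame (``nest_*`` /
    ``plot_*`` covariates, or the special term ``"year"``).  The criterion
    sample size is total exposure days, the standard convention for this
    likelihood.  Complete separation (all nests succeeding, or failing,
    within a stratum) is reported as a boundary warning.
    """
    df = records if isinstance(records, pd.DataFrame) else encounter_records_to_frame(records)
    if len(df) == 0:
        raise ValueError("no encounter records")
    terms = list(terms or [])
    exposure = (df["last_active"] - df["first_found"]).to_numpy(dtype=float)
    window = (df["last_checked"] - df["last_active"]).to_numpy(dtype=float)
    failed = (df["fate"] == "failure").to_numpy()
    if (exposure + window <= 0).all():
        raise ValueError("no positive exposure in the record set")
    if failed.any() and (window[failed] <= 0).any():
        raise ValueError("failure record with a zero-length failure window")
    X, names = _design(df, terms)

    def nll(beta):
        v = -total_log_likelihood(exposure, window, failed, X, beta)
        return v if np.isfinite(v) else 1e12

    beta0 = np.zeros(X.shape[1])
    beta0[0] = special.logit(0.9)
    res = optimize.minimize(nll, beta0, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    warn = []
    if not res.success:
        warn.append(f"optimizer message: {res.message}")
    if not failed.any():
        warn.append("boundary: no failures observed, DSR estimate -> 1")
    elif failed.all():
        warn.append("boundary: no successes observed")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess2(res.x, nll)
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
        warn.append("singular observed information")
    eff_n = int((df["last_checked"] - df["first_found"]).sum())
    return DSRModel(res.x, cov, -res.fun, X.shape[1], eff_n, names,
                    bool(res.success), warn)


def period_survival(dsr_hat: float, se: float, T: int = 30) -> dict:
    """Survival over a T-day exposure period, with delta-method SE.

    estimate = s^T;  se = T * s^(T-1) * se(s).  T defaults to 30 days,
    the full egg-laying-to-fledge exposure period for the study species.
    """
    if not (0 < dsr_hat < 1):
        raise ValueError("daily survival must be in (0, 1)")
    est = dsr_hat ** T
    return {"estimate": float(est), "se": float(T * dsr_hat ** (T - 1) * se)}


def apparent_success(records: list[EncounterRecord] | pd.DataFrame) -> float:
    """Fraction of monitored nests that fledged.

    Biased upward relative to period survival: nests enter the sample only
    after surviving long enough to be found.
    """
    df = records if isinstance(records, pd.DataFrame) else encounter_records_to_frame(records)
    return float((df["fate"] == "success").mean())


# ---------------------------------------------------------------------------
# tiered candidate-set evaluation


def _candidate_structures(covariates: list, exclusive_pairs) -> list:
    cands = [[], ["year"]]
    for c in covariates:
        cands.append(["year", c])
    # two-covariate combinations respecting mutual exclusivity
    for i, a in enumerate(covariates):
        for b in covariates[i + 1:]:
            pair = {a.split("_", 1)[-1], b.split("_", 1)[-1]}
            if any({x, y} <= {a, b} or {x, y} == pair for x, y in exclusive_pairs):
                continue
            cands.append(["year", a, b])
    return cands


def _evaluate_set(df: pd.DataFrame, structures: list) -> ModelSet:
    labels, models, lls, ks = [], [], [], []
    eff_n = int((df["last_checked"] - df["first_found"]).sum())
    for terms in structures:
        m = fit_dsr(df, terms)
        label = " + ".join(t for t in terms) if terms else "Null"
        labels.append(label.replace("year", "Year"))
        models.append(m)
        lls.append(m.log_likelihood)
        ks.append(m.n_params)
    return ModelSet.from_models(labels, models, lls, ks, eff_n, 1.0, "AICc")


def tiered_evaluation(
    records: list[EncounterRecord] | pd.DataFrame,
    nest_covs: list,
    plot_covs: list,
    exclusive_pairs=(("biomass", "exotic_grass_cover"),),
    delta_support: float = 2.0,
) -> dict:
    """Three-tier DSR model evaluation.

    Tier 1 evaluates nest-site covariates, tier 2 plot-scale covariates
    (which may include within-plot SD terms), and tier 3 combines the
    covariates appearing in supported models (delta <= ``delta_support``,
    null and year excluded) of the first two tiers across scales.  The
    null and year-only models are always included in every tier.
    Returns ``{"nest": ModelSet, "plot": ModelSet, "multi": ModelSet}``.
    """
    df = records if isinstance(records, pd.DataFrame) else encounter_records_to_frame(records)
    nest_ms = _evaluate_set(df, _candidate_structures(list(nest_covs), exclusive_pairs))
    plot_ms = _evaluate_set(df, _candidate_structures(list(plot_covs), exclusive_pairs))

    def supported_terms(ms: ModelSet) -> list:
        terms = []
        for e in ms.parsimonious(delta_support):
            for t in e.label.replace("Year", "year").split(" + "):
                if t not in ("Null", "year") and t not in terms:
                    terms.append(t)
        return terms

    sup_nest = supported_terms(nest_ms)
    sup_plot = supported_terms(plot_ms)
    multi_structs = [[], ["year"]]
    for t in sup_nest + sup_plot:
        s = ["year", t]
        if s not in multi_structs:
            multi_structs.append(s)
    for a in sup_nest:
        for b in sup_plot:
            if a == b:
                continue
            bases = {a.split("_", 1)[-1], b.split("_", 1)[-1]}
            if any({x, y} == bases for x, y in exclusive_pairs):
                continue
            s = ["year", a, b]
            if s not in multi_structs:
                multi_structs.append(s)
    multi_ms = _evaluate_set(df, multi_structs)
    return {"nest": nest_ms, "plot": plot_ms, "multi": multi_ms}
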