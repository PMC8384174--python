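"""Information-theoretic model selection and overdispersion machinery.

AICc/QAICc, Akaike weights, a parametric-bootstrap goodness-of-fit test
yielding the variance-inflation factor c-hat, SE inflation, backward
stepwise search over detection-then-density structures, the
non-informative-effect screen (85%/95% Wald interval overlapping zero),
and prediction-scale model averaging with unconditional variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_model import CountDataset
from .dm_density import FittedDMModel, fit_dm, transition_matrix

__all__ = [
    "ModelEntry",
    "ModelSet",
    "GofReport",
    "aicc",
    "qaicc",
    "akaike_weights",
    "chi_square_statistic",
    "simulate_from_fit",
    "parametric_bootstrap_gof",
    "inflate_se",
    "backward_stepwise",
    "noninformative_check",
    "model_average_predictions",
]

#: floor inside the chi-square statistic: cells with p_hat -> 0 would
#: otherwise explode the statistic
CHISQ_EPS = 1e-6


# ---------------------------------------------------------------------------
# information criteria


def aicc(loglik: float, k: int, n: int) -> float:
    """AIC with the finite-sample correction 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"effective sample size n={n} must exceed k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def qaicc(loglik: float, k: int, n: int, c_hat: float = 1.0) -> float:
    """Quasi-AICc: the log-likelihood is deflated by c-hat.

    When overdispersion is actually being corrected (c_hat > 1), one extra
    parameter is counted for the estimated c-hat itself; at c_hat = 1 the
    criterion reduces exactly to AICc.
    """
    c = max(float(c_hat), 1.0)
    k_eff = k + (1 if c > 1.0 else 0)
    if n <= k_eff + 1:
        raise ValueError(f"effective sample size n={n} must exceed k+1={k_eff + 1}")
    return -2.0 * loglik / c + 2.0 * k_eff + 2.0 * k_eff * (k_eff + 1) / (n - k_eff - 1)


def akaike_weights(criteria) -> tuple[np.ndarray, np.ndarray]:
    """Delta values and Akaike weights for a vector of criterion values."""
    c = np.asarray(criteria, dtype=float)
    if c.size == 0:
        raise ValueError("need at least one model")
    delta = c - c.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


# ---------------------------------------------------------------------------
# model-set container


@dataclass
class ModelEntry:
    label: str
    model: object
    log_likelihood: float
    n_params: int
    criterion: float
    delta: float = np.nan
    weight: float = np.nan


@dataclass
class ModelSet:
    """Ranked candidate models with criterion values, deltas and weights."""

    entries: list = field(default_factory=list)
    criterion_name: str = "AICc"

    @classmethod
    def from_models(cls, labels, models, logliks, ks, n, c_hat=1.0,
                    criterion_name=None) -> "ModelSet":
        crits = [qaicc(ll, k, n, c_hat) for ll, k in zip(logliks, ks)]
        entries = [ModelEntry(lab, m, ll, k, cr)
                   for lab, m, ll, k, cr in zip(labels, models, logliks, ks, crits)]
        name = criterion_name or ("QAICc" if c_hat > 1 else "AICc")
        ms = cls(entries, name)
        ms.rank()
        return ms

    def rank(self) -> None:
        # ties broken toward fewer parameters
        self.entries.sort(key=lambda e: (e.criterion, e.n_params))
        delta, w = akaike_weights([e.criterion for e in self.entries])
        for e, d, wi in zip(self.entries, delta, w):
            e.delta, e.weight = float(d), float(wi)

    def best(self) -> ModelEntry:
        return self.entries[0]

    def parsimonious(self, delta_max: float = 2.0) -> list:
        """Models within delta_max criterion units of the best model."""
        return [e for e in self.entries if e.delta <= delta_max]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"model": e.label, "K": e.n_params, self.criterion_name: e.criterion,
              "delta": e.delta, "weight": e.weight} for e in self.entries]
        )

    def to_csv(self, path) -> None:
        self.table().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# goodness of fit


@dataclass
class GofReport:
    chisq_observed: float
    bootstrap_chisq: np.ndarray
    c_hat: float
    p_value: float
    n_failed_refits: int = 0

    def __post_init__(self) -> None:
        if self.c_hat <= 0:
            raise ValueError("c_hat must be positive")


def _expected_counts(fit: FittedDMModel) -> np.ndarray:
    """E[y_it] = p_it * E[N_it] under the fitted dynamics."""
    lam = fit.lambda_hat()
    p = fit.p_hat()
    gamma, omega = fit.parameters.gamma, fit.parameters.omega
    M, T = fit.data.y.shape
    EN = np.empty((M, T))
    EN[:, 0] = lam
    for t in range(1, T):
        EN[:, t] = omega * EN[:, t - 1] + gamma
    return p * EN


def chi_square_statistic(fit: FittedDMModel) -> float:
    """Pearson-type fit statistic over the observed (plot, occasion) cells."""
    E = _expected_counts(fit)
    mask = fit.data.observed_mask
    resid = (fit.data.y - E)[mask]
    denom = np.maximum(E[mask], CHISQ_EPS)
    return float(np.sum(resid ** 2 / denom))


def simulate_from_fit(fit: FittedDMModel, rng: np.random.Generator) -> CountDataset:
    """Draw a replicate count dataset from the fitted generative model.

    The observed mask is preserved so bootstrap replicates share the
    design (including which plots lack a final survey occasion).
    """
    par = fit.parameters
    lam = fit.lambda_hat()
    p = fit.p_hat()
    M, T = fit.data.y.shape
    if par.mixture == "poisson":
        N = rng.poisson(lam)
    else:
        N = rng.negative_binomial(par.alpha, par.alpha / (par.alpha + lam))
    y = np.zeros((M, T), dtype=int)
    y[:, 0] = rng.binomial(N, p[:, 0])
    for t in range(1, T):
        N = rng.binomial(N, par.omega) + rng.poisson(par.gamma, size=M)
        y[:, t] = rng.binomial(N, p[:, t])
    y = np.where(fit.data.observed_mask, y, 0)
    return CountDataset(fit.data.plot_ids, y, fit.data.observed_mask.copy(),
                        {k: v.copy() for k, v in fit.data.survey_covariates.items()},
                        fit.data.plot_covariates)


def parametric_bootstrap_gof(fit: FittedDMModel, B: int = 100,
                             seed: int = 0) -> GofReport:
    """Parametric-bootstrap goodness of fit and variance inflation.

    B datasets are simulated from the fitted model, each refitted (warm
    started at the fitted parameters) and its fit statistic recomputed.
    c_hat = chi2_observed / mean(chi2_bootstrap); the p-value is the
    proportion of bootstrap statistics at least as extreme as observed.
    Refit failures are excluded and counted, never silently dropped.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    obs = chi_square_statistic(fit)
    boots, failed = [], 0
    theta0 = fit.theta()
    for _ in range(B):
        sim = simulate_from_fit(fit, rng)
        try:
            refit = fit_dm(sim, fit.density_covs, fit.detection_covs, fit.mixture,
                           K=fit.parameters.K, start=theta0, compute_covariance=False)
            boots.append(chi_square_statistic(refit))
        except (RuntimeError, ValueError):
            failed += 1
    boots = np.asarray(boots)
    if boots.size == 0:
        raise RuntimeError("all bootstrap refits failed")
    c_hat = obs / float(boots.mean())
    p_value = float(np.mean(boots >= obs))
    return GofReport(obs, boots, c_hat, p_value, failed)


def inflate_se(se, c_hat: float):
    """Overdispersion-adjusted SE: se * sqrt(c_hat), c_hat clamped at 1."""
    return np.asarray(se, dtype=float) * np.sqrt(max(float(c_hat), 1.0))


def noninformative_check(coefficient: float, se: float, c_hat: float = 1.0,
                         level: float = 0.95) -> bool:
    """True when the c-hat-inflated Wald interval contains zero."""
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * float(inflate_se(se, c_hat))
    return bool(coefficient - half <= 0.0 <= coefficient + half)


# ---------------------------------------------------------------------------
# backward stepwise search


def backward_stepwise(
    data: CountDataset,
    detection_covs: list,
    density_covs: list,
    mixture: str = "poisson",
    K: int | None = None,
    c_hat: float = 1.0,
    n_starts: int = 2,
    seed: int = 0,
    n_effective: int | None = None,
) -> tuple[ModelSet, dict]:
    """Two-stage backward elimination: detection submodels first.

    Stage 1 holds the density structure at its full form and drops
    detection terms one at a time, keeping the best-criterion submodel
    until no single drop improves it.  Stage 2 fixes detection at the
    stage-1 winner and repeats for density terms.  All visited models are
    returned ranked; criterion ties break toward fewer parameters.  The
    effective sample size for the criterion is the number of plots (the
    plot is the independent sampling unit).

    Returns (model set, info) where info records the winning structures
    and any candidate fits that failed.
    """
    n = n_effective if n_effective is not None else data.n_plots
    fitted: dict[tuple, FittedDMModel] = {}
    failures: list[tuple] = []

    def crit_of(det, dens):
        key = (tuple(det), tuple(dens))
        if key in fitted:
            m = fitted[key]
            return qaicc(m.log_likelihood, m.n_params, n, c_hat), m
        try:
            m = fit_dm(data, list(dens), list(det), mixture, K=K,
                       n_starts=n_starts, seed=seed, compute_covariance=False)
        except (RuntimeError, ValueError):
            failures.append(key)
            return np.inf, None
        fitted[key] = m
        return qaicc(m.log_likelihood, m.n_params, n, c_hat), m

    def eliminate(active, fixed, stage):
        """Drop-one search over `active`; `fixed` is the other structure."""
        active = list(active)
        if stage == "detection":
            cur_crit, _ = crit_of(active, fixed)
        else:
            cur_crit, _ = crit_of(fixed, active)
        improved = True
        while improved and active:
            improved = False
            best_drop, best_crit = None, cur_crit
            for c in active:
                reduced = [x for x in active if x != c]
                det, dens = (reduced, fixed) if stage == "detection" else (fixed, reduced)
                cr, _ = crit_of(det, dens)
                # strict improvement, with ties favouring the smaller model
                if cr < best_crit or np.isclose(cr, best_crit):
                    best_drop, best_crit = c, min(cr, best_crit)
            if best_drop is not None:
                active.remove(best_drop)
                cur_crit = best_crit
                improved = True
        return active

    det_final = eliminate(detection_covs, list(density_covs), "detection")
    dens_final = eliminate(density_covs, det_final, "density")
    crit_of(det_final, dens_final)  # ensure the winner is in the visited set

    labels, models, lls, ks = [], [], [], []
    for (det, dens), m in fitted.items():
        det_lab = " + ".join(det) if det else "1"
        dens_lab = " + ".join(dens) if dens else "1"
        labels.append(f"p({det_lab}) lambda({dens_lab})")
        models.append(m)
        lls.append(m.log_likelihood)
        ks.append(m.n_params)
    ms = ModelSet.from_models(labels, models, lls, ks, n, c_hat)
    info = {
        "detection_selected": det_final,
        "density_selected": dens_final,
        "n_fitted": len(fitted),
        "failures": failures,
        "parsimonious": [e.label for e in ms.parsimonious(2.0)],
    }
    return ms, info


# ---------------------------------------------------------------------------
# model averaging


def model_average_predictions(weights, predictions, variances=None):
    """Akaike-weighted prediction with unconditional variance.

    prediction = sum_i w_i yhat_i;
    var = sum_i w_i (var_i + (yhat_i - ybar)^2), the usual model-averaging
    variance that carries model-selection uncertainty.
    Inputs may be scalars per model or per-plot vectors.
    """
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError(f"model weights must sum to 1 (got {w.sum()})")
    yhat = np.asarray(predictions, dtype=float)
    avg = np.tensordot(w, yhat, axes=(0, 0))
    if variances is None:
        var = np.tensordot(w, (yhat - avg) ** 2, axes=(0, 0))
    else:
        v = np.asarray(variances, dtype=float)
        var = np.tensordot(w, v + (yhat - avg) ** 2, axes=(0, 0))
    return avg, var
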