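"""Open-population N-mixture (Dail-Madsen) model for replicated nest counts.

The latent number of active nests on plot i at survey occasion t is an
integer N_it.  Initial abundance follows a Poisson (or negative-binomial)
mixture with log-linear covariates, the latent state evolves between
occasions as binomial survivors plus Poisson recruits,

    N_i1 ~ Mixture(lambda_i),     lambda_i = exp(x_i' beta_lambda)
    N_it | N_i,t-1 = Binomial(N_i,t-1, omega) + Poisson(gamma),

and each count is a binomial thinning of the current latent state,

    y_it | N_it ~ Binomial(N_it, p_it),   logit(p_it) = w_it' beta_p.

The latent state is truncated at K and the likelihood is computed by a
forward recursion over {0..K}; no renormalization of the truncated pmfs is
applied, so the truncation mass is visible (and checked) rather than
hidden.  Survival omega and recruitment gamma are time-constant scalars:
an estimated gamma > 0 or omega < 1 is direct evidence that the nest
population is not closed over the survey window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats, special
from statsmodels.tools.numdiff import approx_hess2

from .data_model import CountDataset

__all__ = [
    "DMParameters",
    "FittedDMModel",
    "LatentPosterior",
    "initial_pmf",
    "transition_pmf",
    "transition_matrix",
    "site_log_likelihood",
    "dm_log_likelihood",
    "fit_dm",
    "check_K_stability",
    "closure_change",
    "closure_test",
    "latent_posterior",
    "predict_density",
    "quadratic_vertex",
    "build_design_matrices",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class DMParameters:
    """Model parameters on their unconstrained (link) scales."""

    beta_lambda: np.ndarray          # log link, initial abundance
    beta_p: np.ndarray               # logit link, detection
    log_gamma: float                 # recruitment rate >= 0
    logit_omega: float               # survival probability in [0, 1]
    log_alpha: float | None = None   # NB dispersion, None for Poisson
    K: int = 50

    @property
    def gamma(self) -> float:
        return float(np.exp(self.log_gamma))

    @property
    def omega(self) -> float:
        return float(special.expit(self.logit_omega))

    @property
    def alpha(self) -> float | None:
        return None if self.log_alpha is None else float(np.exp(self.log_alpha))

    @property
    def mixture(self) -> str:
        return "poisson" if self.log_alpha is None else "negbin"

    def pack(self) -> np.ndarray:
        theta = np.concatenate([
            self.beta_lambda, self.beta_p, [self.logit_omega, self.log_gamma]
        ])
        if self.log_alpha is not None:
            theta = np.append(theta, self.log_alpha)
        return theta

    @classmethod
    def unpack(cls, theta: np.ndarray, d_lambda: int, d_p: int,
               mixture: str, K: int) -> "DMParameters":
        theta = np.asarray(theta, dtype=float)
        bl = theta[:d_lambda]
        bp = theta[d_lambda:d_lambda + d_p]
        lo, lg = theta[d_lambda + d_p], theta[d_lambda + d_p + 1]
        la = theta[d_lambda + d_p + 2] if mixture == "negbin" else None
        return cls(bl, bp, float(lg), float(lo), la, K)


@dataclass
class FittedDMModel:
    """A fitted open N-mixture model with its uncertainty."""

    parameters: DMParameters
    covariance: np.ndarray
    log_likelihood: float
    n_params: int
    data: CountDataset
    density_covs: list
    detection_covs: list
    mixture: str
    converged: bool
    gradient_norm: float
    message: str = ""
    warnings: list = field(default_factory=list)
    param_names: list = field(default_factory=list)

    def theta(self) -> np.ndarray:
        return self.parameters.pack()

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, np.inf))

    def design_matrices(self):
        return build_design_matrices(self.data, self.density_covs, self.detection_covs)

    def lambda_hat(self) -> np.ndarray:
        X, _ = self.design_matrices()
        return np.exp(X @ self.parameters.beta_lambda)

    def p_hat(self) -> np.ndarray:
        _, W = self.design_matrices()
        return special.expit(np.einsum("itk,k->it", W, self.parameters.beta_p))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.theta(), "se": self.se()},
                            index=self.param_names)


# ---------------------------------------------------------------------------
# elementary pmfs


def initial_pmf(lam: float, mixture: str = "poisson", K: int = 50,
                alpha: float | None = None) -> np.ndarray:
    """P(N_1 = n) for n = 0..K under the chosen mixture (not renormalized).

    The negative binomial is parameterized by its mean ``lam`` and
    dispersion ``alpha`` (variance lam + lam^2 / alpha), the standard
    ecological overdispersion form.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    n = np.arange(K + 1)
    if mixture == "poisson":
        if alpha is not None:
            raise ValueError("alpha is only meaningful for the negbin mixture")
        return stats.poisson.pmf(n, lam)
    if mixture == "negbin":
        if alpha is None or alpha <= 0:
            raise ValueError("negbin mixture requires dispersion alpha > 0")
        return stats.nbinom.pmf(n, alpha, alpha / (alpha + lam))
    raise ValueError(f"unknown mixture {mixture!r}")


def transition_matrix(gamma: float, omega: float, K: int) -> np.ndarray:
    """(K+1) x (K+1) matrix T[m, n] = P(N_t = n | N_{t-1} = m).

    Next abundance = Binomial(m, omega) survivors + Poisson(gamma) recruits;
    T[m, n] = sum_s Binom(s; m, omega) Pois(n - s; gamma).  Rows sum to
    1 minus the truncation mass beyond K.
    """
    ns = np.arange(K + 1)
    surv = stats.binom.pmf(ns[None, :], ns[:, None], omega)   # [m, s], 0 for s > m
    rec = stats.poisson.pmf(ns, gamma)
    # C[s, n] = Pois(n - s): upper-triangular Toeplitz
    C = np.zeros((K + 1, K + 1))
    for s in range(K + 1):
        C[s, s:] = rec[: K + 1 - s]
    return surv @ C


def transition_pmf(m: int, gamma: float, omega: float, K: int) -> np.ndarray:
    """P(N_t = n | N_{t-1} = m) for n = 0..K."""
    if not (0 <= m <= K):
        raise ValueError("require 0 <= m <= K")
    if gamma < 0 or not (0 <= omega <= 1):
        raise ValueError("require gamma >= 0 and omega in [0, 1]")
    s = np.arange(min(m, K) + 1)
    surv = stats.binom.pmf(s, m, omega)
    rec = stats.poisson.pmf(np.arange(K + 1), gamma)
    return np.convolve(surv, rec)[: K + 1]


# ---------------------------------------------------------------------------
# likelihood


def _forward_masses(y, mask, lam, p, gamma, omega, K, mixture, alpha):
    """Vectorized forward recursion; returns (M, K+1) terminal mass matrix."""
    M, T = y.shape
    ns = np.arange(K + 1)
    if mixture == "poisson":
        f = stats.poisson.pmf(ns[None, :], lam[:, None])
    else:
        f = stats.nbinom.pmf(ns[None, :], alpha, alpha / (alpha + lam[:, None]))
    trans = transition_matrix(gamma, omega, K) if T > 1 else None
    for t in range(T):
        if t > 0:
            f = f @ trans
        obs = mask[:, t]
        if obs.any():
            det = stats.binom.pmf(y[:, t, None], ns[None, :], p[:, t, None])
            f = np.where(obs[:, None], f * det, f)
    return f


def dm_log_likelihood(y: np.ndarray, mask: np.ndarray, lam: np.ndarray,
                      p: np.ndarray, gamma: float, omega: float, K: int,
                      mixture: str = "poisson",
                      alpha: float | None = None) -> np.ndarray:
    """Per-site log-likelihood contributions, length M."""
    if np.any(y[mask] > K):
        raise ValueError("observed count exceeds truncation bound K")
    f = _forward_masses(np.asarray(y), np.asarray(mask, bool),
                        np.asarray(lam, float), np.asarray(p, float),
                        gamma, omega, K, mixture, alpha)
    with np.errstate(divide="ignore"):
        return np.log(f.sum(axis=1))


def site_log_likelihood(y_i: np.ndarray, mask_i: np.ndarray, lam_i: float,
                        p_i: np.ndarray, gamma: float, omega: float, K: int,
                        mixture: str = "poisson",
                        alpha: float | None = None) -> float:
    """Log-likelihood of one plot's count history (forward recursion)."""
    y = np.asarray(y_i, dtype=int)[None, :]
    mask = np.asarray(mask_i, dtype=bool)[None, :]
    p = np.asarray(p_i, dtype=float)[None, :]
    return float(dm_log_likelihood(y, mask, np.array([lam_i]), p,
                                   gamma, omega, K, mixture, alpha)[0])


# ---------------------------------------------------------------------------
# design matrices


def _column(data: CountDataset, name: str) -> np.ndarray:
    """Per-plot covariate column; 'x^2' means the square of column x."""
    if name.endswith("^2"):
        return _column(data, name[:-2]) ** 2
    if data.plot_covariates is None or name not in data.plot_covariates.columns:
        raise KeyError(f"unknown plot covariate {name!r}")
    return data.plot_covariates[name].to_numpy(dtype=float)


def build_design_matrices(data: CountDataset, density_covs: list,
                          detection_covs: list) -> tuple[np.ndarray, np.ndarray]:
    """(X, W): density design (M, 1+d) and detection design (M, T, 1+d').

    Both include a leading intercept.  Detection covariates may be survey
    covariates (per plot-occasion) or plot covariates (broadcast across
    occasions, e.g. shrub cover).  Quadratics are requested as ``name^2``.
    """
    M, T = data.y.shape
    X = np.column_stack([np.ones(M)] + [_column(data, c) for c in density_covs])
    cols = [np.ones((M, T))]
    for c in detection_covs:
        if c in data.survey_covariates:
            arr = data.survey_covariates[c].copy()
            arr[~data.observed_mask] = 0.0  # unused cells; keep finite
            cols.append(arr)
        else:
            cols.append(np.broadcast_to(_column(data, c)[:, None], (M, T)).copy())
    W = np.stack(cols, axis=-1)
    return X, W


# ---------------------------------------------------------------------------
# fitting

_BOUND = 20.0  # |link-scale parameter| cap: keeps exp/expit finite


def _nll_factory(data, density_covs, detection_covs, mixture, K):
    X, W = build_design_matrices(data, density_covs, detection_covs)
    d_l, d_p = X.shape[1], W.shape[2]
    y, mask = data.y, data.observed_mask

    def nll(theta):
        par = DMParameters.unpack(theta, d_l, d_p, mixture, K)
        lam = np.exp(np.clip(X @ par.beta_lambda, -30, 30))
        p = special.expit(np.einsum("itk,k->it", W, par.beta_p))
        ll = dm_log_likelihood(y, mask, lam, p, par.gamma, par.omega, K,
                               mixture, par.alpha)
        total = ll.sum()
        if not np.isfinite(total):
            return 1e12
        return -total

    return nll, d_l, d_p


def _param_names(density_covs, detection_covs, mixture):
    names = ["lambda:(Intercept)"] + [f"lambda:{c}" for c in density_covs]
    names += ["p:(Intercept)"] + [f"p:{c}" for c in detection_covs]
    names += ["logit_omega", "log_gamma"]
    if mixture == "negbin":
        names.append("log_alpha")
    return names


def fit_dm(
    data: CountDataset,
    density_covs: list | None = None,
    detection_covs: list | None = None,
    mixture: str = "poisson",
    K: int | None = None,
    n_starts: int = 5,
    seed: int = 0,
    start: np.ndarray | None = None,
    compute_covariance: bool = True,
    fix_gamma: float | None = None,
    fix_omega: float | None = None,
    fixed: dict[int, float] | None = None,
) -> FittedDMModel:
    """Maximum-likelihood fit of the open N-mixture model.

    Optimization is quasi-Newton (L-BFGS-B) on the unconstrained link
    scale, launched from a moment-based start (lambda start = mean count /
    0.2, i.e. assuming detection near the plausible low end) plus
    ``n_starts - 1`` seeded normal perturbations of it; the best optimum is
    kept.  Standard errors come from the numerically differentiated
    observed information; a singular information matrix is reported as an
    identifiability warning, never papered over.

    Covariates are expected to be standardized (see
    :func:`nestmix.data_model.standardize`); quadratic terms are entered as
    ``(x, x^2)`` pairs of the standardized covariate.
    """
    density_covs = list(density_covs or [])
    detection_covs = list(detection_covs or [])
    if K is None:
        K = data.max_count() + 100
    if K < data.max_count():
        raise ValueError("K below the maximum observed count")

    nll, d_l, d_p = _nll_factory(data, density_covs, detection_covs, mixture, K)
    n_free = d_l + d_p + 2 + (1 if mixture == "negbin" else 0)

    if start is None:
        mean_count = float(data.y[data.observed_mask].mean()) if data.observed_mask.any() else 0.0
        lam0 = max(mean_count / 0.2, 1e-3)
        base = np.zeros(n_free)
        base[0] = np.log(lam0)
        base[d_l] = special.logit(0.2)
        base[d_l + d_p] = special.logit(0.8)      # omega
        base[d_l + d_p + 1] = np.log(0.1)         # gamma
        if mixture == "negbin":
            base[-1] = np.log(1.0)
        rng = np.random.default_rng(seed)
        starts = [base] + [base + rng.normal(0, 0.5, n_free) for _ in range(n_starts - 1)]
    else:
        starts = [np.asarray(start, dtype=float)]

    bounds = [(-_BOUND, _BOUND)] * n_free
    # recruitment can legitimately sit on its gamma -> 0 boundary
    bounds[d_l + d_p + 1] = (-_BOUND, 5.0)
    # dynamics parameters may be pinned (e.g. recovery experiments fitting
    # the generating structure with known gamma = 0); pinned parameters do
    # not count as free and are excluded from the information matrix
    i_om, i_ga = d_l + d_p, d_l + d_p + 1
    fixed_idx = []
    if fix_omega is not None:
        v = float(np.clip(special.logit(fix_omega), -_BOUND, _BOUND))
        bounds[i_om] = (v, v)
        fixed_idx.append(i_om)
    if fix_gamma is not None:
        v = float(np.clip(np.log(fix_gamma) if fix_gamma > 0 else -_BOUND,
                          -_BOUND, 5.0))
        bounds[i_ga] = (v, v)
        fixed_idx.append(i_ga)
    if fixed:
        # arbitrary parameters pinned at link-scale values (profile fits)
        for i, v in fixed.items():
            bounds[i] = (float(v), float(v))
            fixed_idx.append(i)
    for i in fixed_idx:
        for s0 in starts:
            s0[i] = bounds[i][0]

    best = None
    for s0 in starts:
        res = optimize.minimize(nll, np.clip(s0, -_BOUND, _BOUND), method="L-BFGS-B",
                                bounds=bounds, options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("open N-mixture fit failed to converge from all starts")

    theta = best.x
    warn: list[str] = []
    if not best.success:
        warn.append(f"optimizer message: {best.message}")
    grad_norm = float(np.linalg.norm(np.atleast_1d(best.jac))) if best.jac is not None else np.nan

    at_bound = np.abs(theta) >= _BOUND - 1e-6
    if at_bound[:d_l].any() or (at_bound[i_ga] and i_ga not in fixed_idx):
        warn.append("boundary estimate: a rate parameter reached its link-scale bound")
    if data.observed_mask.any() and not data.y[data.observed_mask].any():
        warn.append("boundary: all observed counts are zero; lambda -> 0")

    free_idx = [i for i in range(n_free) if i not in fixed_idx]
    cov = np.full((n_free, n_free), np.nan)
    if compute_covariance:
        def nll_free(th_free):
            full = theta.copy()
            full[free_idx] = th_free
            return nll(full)

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hess = approx_hess2(theta[free_idx], nll_free)
            cov_free = np.linalg.inv(hess)
            if np.any(np.diag(cov_free) < 0):
                warn.append("observed information not positive definite; SEs unreliable")
            cov[np.ix_(free_idx, free_idx)] = cov_free
            for i in fixed_idx:
                cov[i, :] = cov[:, i] = 0.0
        except np.linalg.LinAlgError:
            warn.append("singular observed information: parameters may not be identifiable")

    params = DMParameters.unpack(theta, d_l, d_p, mixture, K)
    return FittedDMModel(
        parameters=params,
        covariance=cov,
        log_likelihood=-best.fun,
        n_params=n_free - len(fixed_idx),
        data=data,
        density_covs=density_covs,
        detection_covs=detection_covs,
        mixture=mixture,
        converged=bool(best.success),
        gradient_norm=grad_norm,
        message=str(best.message),
        warnings=warn,
        param_names=_param_names(density_covs, detection_covs, mixture),
    )


# ---------------------------------------------------------------------------
# diagnostics


def check_K_stability(fit: FittedDMModel, increments=(20, 50),
                      tolerance: float = 0.01) -> dict:
    """Refit at larger truncation bounds and report coefficient drift.

    A well-behaved truncated likelihood is insensitive to K once the
    truncation mass is negligible; systematic coefficient growth with K
    (the negative-binomial pathology) is flagged as ``unstable``.  This is
    a diagnostic: it reports, it never raises on instability.
    """
    rows = []
    theta0 = fit.theta()
    for inc in increments:
        refit = fit_dm(fit.data, fit.density_covs, fit.detection_covs,
                       fit.mixture, K=fit.parameters.K + int(inc),
                       start=theta0, compute_covariance=False)
        rows.append({
            "K": refit.parameters.K,
            "max_abs_coef_change": float(np.max(np.abs(refit.theta() - theta0))),
            "loglik_change": float(refit.log_likelihood - fit.log_likelihood),
        })
    report = pd.DataFrame(rows)
    return {
        "base_K": fit.parameters.K,
        "table": report,
        "max_abs_coef_change": float(report["max_abs_coef_change"].max()),
        "stable": bool((report["max_abs_coef_change"] <= tolerance).all()),
        "tolerance": tolerance,
    }


def closure_change(gamma: float, omega: float) -> float:
    """Expected percent change in nest numbers per between-survey interval.

    E[N_t | N_{t-1}] = omega * N_{t-1} + gamma, so for a typical plot the
    per-interval relative change is approximately (omega + gamma - 1);
    negative values are a percent decrease.  gamma = 0, omega = 0.87 gives
    -13: a 13% decline between successive surveys.
    """
    return (omega + gamma - 1.0) * 100.0


def closure_test(fit: FittedDMModel, level: float = 0.95) -> dict:
    """Wald test of within-window population closure.

    The population is declared open (``closed = False``) when the
    confidence interval for gamma excludes 0 from above or the interval
    for omega excludes 1 from below.
    """
    d = len(fit.parameters.beta_lambda) + len(fit.parameters.beta_p)
    i_om, i_ga = d, d + 1
    se = fit.se()
    z = stats.norm.ppf(0.5 + level / 2)
    lo_link, lg_link = fit.parameters.logit_omega, fit.parameters.log_gamma
    se_om, se_ga = se[i_om], se[i_ga]
    omega_ci = special.expit([lo_link - z * se_om, lo_link + z * se_om])
    gamma_ci = np.exp(np.clip([lg_link - z * se_ga, lg_link + z * se_ga], -700, 700))
    gamma_hat, omega_hat = fit.parameters.gamma, fit.parameters.omega
    # delta-method SEs on the natural scale
    se_gamma = gamma_hat * se_ga
    se_omega = omega_hat * (1 - omega_hat) * se_om
    open_gamma = bool(np.isfinite(gamma_ci[0]) and gamma_ci[0] > 0 and fit.parameters.log_gamma > -_BOUND + 1e-6)
    open_omega = bool(np.isfinite(omega_ci[1]) and omega_ci[1] < 1)
    return {
        "gamma_hat": gamma_hat,
        "omega_hat": omega_hat,
        "gamma_se": float(se_gamma),
        "omega_se": float(se_omega),
        "gamma_ci": tuple(float(v) for v in gamma_ci),
        "omega_ci": tuple(float(v) for v in omega_ci),
        "percent_change_per_interval": closure_change(gamma_hat, omega_hat),
        "closed": not (open_gamma or open_omega),
    }


# ---------------------------------------------------------------------------
# empirical-Bayes latent abundance


@dataclass
class LatentPosterior:
    """Per-plot posteriors over the latent nest abundance.

    ``occasion_posteriors`` has shape (M, T, K+1); ``modes`` are the
    posterior modes of initial abundance (ties broken toward the smaller
    N, a conservative abundance prediction); ``means`` the posterior means.
    """

    occasion_posteriors: np.ndarray
    modes: np.ndarray
    means: np.ndarray

    def initial(self) -> np.ndarray:
        return self.occasion_posteriors[:, 0, :]


def latent_posterior(fit: FittedDMModel) -> LatentPosterior:
    """Empirical-Bayes posterior P(N_it | y_i, theta_hat), forward-backward.

    Conditional on the fitted parameters, the latent chain given the
    counts is a finite HMM over {0..K}; the usual smoothing recursion
    applies.  The occasion-1 posterior mode is the best integer prediction
    of the true number of nests a plot held, corrected for detection.
    """
    data = fit.data
    par = fit.parameters
    K = par.K
    M, T = data.y.shape
    ns = np.arange(K + 1)
    X, W = fit.design_matrices()
    lam = np.exp(X @ par.beta_lambda)
    p = special.expit(np.einsum("itk,k->it", W, par.beta_p))

    if par.mixture == "poisson":
        init = stats.poisson.pmf(ns[None, :], lam[:, None])
    else:
        init = stats.nbinom.pmf(ns[None, :], par.alpha, par.alpha / (par.alpha + lam[:, None]))
    trans = transition_matrix(par.gamma, par.omega, K) if T > 1 else None

    det = np.ones((M, T, K + 1))
    for t in range(T):
        obs = data.observed_mask[:, t]
        if obs.any():
            dt = stats.binom.pmf(data.y[:, t, None], ns[None, :], p[:, t, None])
            det[:, t, :] = np.where(obs[:, None], dt, 1.0)

    alpha_f = np.empty((M, T, K + 1))
    alpha_f[:, 0, :] = init * det[:, 0, :]
    for t in range(1, T):
        alpha_f[:, t, :] = (alpha_f[:, t - 1, :] @ trans) * det[:, t, :]
    beta_b = np.empty((M, T, K + 1))
    beta_b[:, T - 1, :] = 1.0
    for t in range(T - 2, -1, -1):
        beta_b[:, t, :] = (det[:, t + 1, :] * beta_b[:, t + 1, :]) @ trans.T

    post = alpha_f * beta_b
    norm = post.sum(axis=2, keepdims=True)
    norm = np.where(norm > 0, norm, 1.0)
    post = post / norm
    first = post[:, 0, :]
    modes = first.argmax(axis=1)  # argmax takes the first (smallest N) on ties
    means = first @ ns
    return LatentPosterior(post, modes.astype(int), means)


# ---------------------------------------------------------------------------
# prediction


def predict_density(fit: FittedDMModel, plot_covariates: pd.DataFrame,
                    c_hat: float = 1.0) -> pd.DataFrame:
    """Expected initial nest abundance per plot with delta-method SE.

    ``plot_covariates`` must be on the same standardized scale as the data
    the model was fitted to; quadratic terms are derived internally.
    Intervals can be widened for overdispersion via ``c_hat``.
    """
    cols = []
    for c in fit.density_covs:
        base = c[:-2] if c.endswith("^2") else c
        if base not in plot_covariates.columns:
            raise KeyError(f"covariate {base!r} missing from prediction frame")
        v = plot_covariates[base].to_numpy(dtype=float)
        cols.append(v ** 2 if c.endswith("^2") else v)
    X = np.column_stack([np.ones(len(plot_covariates))] + cols) if cols else \
        np.ones((len(plot_covariates), 1))
    beta = fit.parameters.beta_lambda
    eta = X @ beta
    lam = np.exp(eta)
    d = len(beta)
    V = fit.covariance[:d, :d] * max(c_hat, 1.0)
    var_eta = np.einsum("ij,jk,ik->i", X, V, X)
    se = lam * np.sqrt(np.clip(var_eta, 0, np.inf))
    return pd.DataFrame({"lambda_hat": lam, "se": se}, index=plot_covariates.index)


def quadratic_vertex(b1: float, b2: float) -> float:
    """Stationary point of b1*x + b2*x^2 (a maximum when b2 < 0)."""
    if b2 == 0:
        raise ValueError("no vertex: quadratic coefficient is zero")
    return -b1 / (2.0 * b2)
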