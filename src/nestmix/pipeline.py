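"""End-to-end orchestration: density -> survival -> productivity.

Each stage consumes validated inputs and an :class:`AnalysisConfig` and
returns a plain-dict report fragment (JSON-serializable apart from the
embedded tables, which export to CSV).  There is no hidden state between
stages: productivity takes the density and survival fragments explicitly.
All randomness flows from the single configured seed.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import CountDataset, standardize, encounter_records_to_frame
from .dm_density import (fit_dm, check_K_stability, closure_test,
                         latent_posterior, predict_density)
from .selection_gof import (aicc, akaike_weights, backward_stepwise,
                            parametric_bootstrap_gof, inflate_se,
                            model_average_predictions)
from .nest_survival import (fit_dsr, tiered_evaluation, period_survival,
                            apparent_success)
from .productivity import (build_productivity_table, productivity_regression,
                           scale_to_management_unit)

__all__ = ["AnalysisConfig", "run_density", "run_survival", "run_productivity",
           "log"]


def log(msg: str) -> None:
    print(f"[nestmix] {msg}", file=sys.stderr)


@dataclass
class AnalysisConfig:
    """Validated configuration for an end-to-end analysis run."""

    seed: int = 1
    mixture: str = "poisson"
    K: int | None = None
    bootstrap_B: int = 100
    period_days: int = 30
    density_covs: list = field(default_factory=list)
    detection_covs: list = field(default_factory=list)
    survival_nest_covs: list = field(default_factory=list)
    survival_plot_covs: list = field(default_factory=list)
    productivity_predictor: str = "biomass"
    n_starts: int = 5
    collinearity_threshold: float = 0.6

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown configuration key(s): {sorted(bad)}")
        return cls(**raw)

    def validate_against(self, data: CountDataset) -> None:
        cols = set(data.plot_covariates.columns) if data.plot_covariates is not None else set()
        survey = set(data.survey_covariates)
        for c in self.density_covs:
            base = c[:-2] if c.endswith("^2") else c
            if base not in cols:
                raise ValueError(f"density covariate {c!r} not found in plot covariates")
        for c in self.detection_covs:
            base = c[:-2] if c.endswith("^2") else c
            if base not in cols and base not in survey:
                raise ValueError(f"detection covariate {c!r} not found in the inputs")


def _stamp(config: AnalysisConfig) -> dict:
    return {"software": "nestmix", "version": __version__, "seed": config.seed}


def run_density(data: CountDataset, config: AnalysisConfig) -> dict:
    """Full nest-density workflow on one count dataset.

    Poisson-vs-NB distribution comparison with K-stability diagnostics,
    bootstrap goodness of fit and c-hat on the selected structure,
    backward stepwise model selection under QAICc, the closure test, and
    empirical-Bayes latent abundance for the top model.
    """
    config.validate_against(data)
    work = data
    std_params = None
    if data.plot_covariates is not None and len(data.plot_covariates.columns):
        z, std_params = standardize(data.plot_covariates)
        work = CountDataset(data.plot_ids, data.y, data.observed_mask,
                            data.survey_covariates, z)

    log("comparing Poisson vs negative-binomial mixtures")
    full_dens = config.density_covs
    full_det = config.detection_covs
    fits = {}
    for mix in ("poisson", "negbin"):
        fits[mix] = fit_dm(work, full_dens, full_det, mix, K=config.K,
                           n_starts=config.n_starts, seed=config.seed)
    n_eff = work.n_plots
    crits = {m: aicc(f.log_likelihood, f.n_params, n_eff) for m, f in fits.items()}
    _, w = akaike_weights(list(crits.values()))
    mixture_weights = dict(zip(crits, map(float, w)))
    stability = {m: check_K_stability(f, increments=(20,)) for m, f in fits.items()}
    # an unstable NB fit falls back to Poisson regardless of its AICc support
    chosen = config.mixture
    if chosen == "negbin" and not stability["negbin"]["stable"]:
        log("negative-binomial fit unstable in K; falling back to Poisson")
        chosen = "poisson"

    log(f"bootstrap goodness of fit (B = {config.bootstrap_B})")
    gof = parametric_bootstrap_gof(fits[chosen], B=config.bootstrap_B,
                                   seed=config.seed)
    c_hat = max(gof.c_hat, 1.0)

    log("backward stepwise selection (detection, then density)")
    model_set, step_info = backward_stepwise(
        work, full_det, full_dens, chosen, K=config.K, c_hat=c_hat,
        n_starts=min(config.n_starts, 2), seed=config.seed)
    best = model_set.best().model
    best = fit_dm(work, best.density_covs, best.detection_covs, chosen,
                  K=config.K, start=best.theta())  # refresh covariance

    closure = closure_test(best)
    post = latent_posterior(best)
    predictions = predict_density(best, work.plot_covariates, c_hat=c_hat) \
        if work.plot_covariates is not None else None

    return {
        "stamp": _stamp(config),
        "mixture_comparison": {"aicc": {k: float(v) for k, v in crits.items()},
                               "weights": mixture_weights,
                               "stability": {m: {"stable": s["stable"],
                                                 "max_abs_coef_change": s["max_abs_coef_change"]}
                                             for m, s in stability.items()},
                               "chosen": chosen},
        "gof": {"chisq": gof.chisq_observed, "c_hat": gof.c_hat,
                "p_value": gof.p_value, "failed_refits": gof.n_failed_refits},
        "c_hat_used": c_hat,
        "selection": {"table": model_set.table(), "info": step_info},
        "best_model": best,
        "best_summary": best.summary_frame(),
        "closure": closure,
        "latent": post,
        "N_hat": post.modes,
        "N_mean": post.means,
        "predictions": predictions,
        "standardization": std_params,
        "mean_count_per_plot": float(np.where(data.observed_mask, data.y, 0).max(axis=1).mean()),
    }


def run_survival(records, config: AnalysisConfig,
                 plot_covariates: pd.DataFrame | None = None) -> dict:
    """Tiered DSR model evaluation plus model-averaged per-plot survival."""
    df = encounter_records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    if len(df) == 0:
        return {"stamp": _stamp(config), "n_nests": 0, "message": "no encounter records"}

    # standardize record-level covariates so effects are comparable
    cov_cols = [c for c in df.columns
                if c.startswith(("nest_", "plot_")) and not c.endswith("_id")]
    std = df.copy()
    for c in cov_cols:
        sd = std[c].std(ddof=1)
        if sd > 0:
            std[c] = (std[c] - std[c].mean()) / sd

    nest_terms = [f"nest_{c}" for c in config.survival_nest_covs]
    plot_terms = [f"plot_{c}" for c in config.survival_plot_covs]
    nest_terms = [t for t in nest_terms if t in std.columns]
    plot_terms = [t for t in plot_terms if t in std.columns]
    log("tiered DSR candidate evaluation")
    tiers = tiered_evaluation(std, nest_terms, plot_terms)

    null_fit = fit_dsr(std, [])
    dsr0, dsr0_se = null_fit.dsr_intercept, null_fit.dsr_intercept_se()
    ps = period_survival(dsr0, dsr0_se, config.period_days)

    # model-averaged per-plot DSR over the plot-scale tier
    per_plot = None
    if plot_covariates is not None:
        plot_ms = tiers["plot"]
        zc = (plot_covariates - plot_covariates.mean()) / plot_covariates.std(ddof=1)
        preds, variances, weights = [], [], []
        for e in plot_ms.entries:
            m = e.model
            X = _plot_design(m, zc)
            preds.append(m.predict(X))
            variances.append(m.predict_var(X))
            weights.append(e.weight)
        avg, var = model_average_predictions(np.array(weights), np.array(preds),
                                             np.array(variances))
        per_plot = pd.DataFrame({"dsr_avg": avg, "dsr_var": var},
                                index=plot_covariates.index)

    return {
        "stamp": _stamp(config),
        "n_nests": len(df),
        "apparent_success": apparent_success(df),
        "tiers": {k: v.table() for k, v in tiers.items()},
        "tier_sets": tiers,
        "dsr_null": {"estimate": dsr0, "se": dsr0_se},
        "period_survival": ps,
        "per_plot_dsr": per_plot,
    }


def _plot_design(model, z: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(z))]
    for name in model.term_names[1:]:
        if name.startswith("year["):
            cols.append(np.zeros(len(z)))  # predictions at the reference year
        else:
            base = name[len("plot_"):] if name.startswith("plot_") else name
            cols.append(z[base].to_numpy(dtype=float))
    return np.column_stack(cols)


def run_productivity(density_frag: dict, survival_frag: dict,
                     config: AnalysisConfig,
                     plot_covariates: pd.DataFrame) -> dict:
    """Compose density and survival fragments into plot-scale productivity."""
    for frag, name in ((density_frag, "density"), (survival_frag, "survival")):
        if frag is None:
            raise ValueError(f"missing {name} fragment: run that stage first")
    if survival_frag.get("per_plot_dsr") is not None:
        dsr_avg = survival_frag["per_plot_dsr"]["dsr_avg"].to_numpy()
    else:
        dsr_avg = np.full(len(plot_covariates), survival_frag["dsr_null"]["estimate"])
    table = build_productivity_table(
        plot_covariates.index, density_frag["N_hat"], dsr_avg,
        plot_covariates, T=config.period_days, N_mean=density_frag["N_mean"])
    report = productivity_regression(table, config.productivity_predictor)
    per_100 = scale_to_management_unit(report.slope, 100.0, 9.0)
    per_1000ha = scale_to_management_unit(report.slope, 1000.0, 1000.0)
    return {
        "stamp": _stamp(config),
        "table": table,
        "regression": report,
        "slope_raw": report.slope,
        "slope_per_100_units_per_plot": per_100,
        "delta_nests_1000ha_per_1000_units": per_1000ha,
    }


def write_fragment(frag: dict, out_dir, name: str) -> None:
    """Serialize a report fragment: tables to CSV, scalars to JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    def jsonable(v):
        if isinstance(v, (bool, int, float, str, type(None), np.integer, np.floating)):
            return True
        if isinstance(v, (list, tuple)):
            return all(jsonable(x) for x in v)
        if isinstance(v, dict):
            return all(isinstance(k, str) and jsonable(x) for k, x in v.items())
        return False

    scalars = {}
    for k, v in frag.items():
        if isinstance(v, pd.DataFrame):
            v.to_csv(out / f"{name}_{k}.csv")
        elif isinstance(v, dict) and all(isinstance(x, pd.DataFrame) for x in v.values()) and v:
            for sub, tbl in v.items():
                tbl.to_csv(out / f"{name}_{k}_{sub}.csv")
        elif isinstance(v, np.ndarray) and v.ndim == 1:
            scalars[k] = v.tolist()
        elif jsonable(v):
            scalars[k] = v
    with open(out / f"{name}.json", "w", encoding="utf-8") as fh:
        json.dump(scalars, fh, indent=2, default=float)
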