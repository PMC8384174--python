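"""Vegetation-sampling support statistics.

Covers three standalone pieces of the vegetation workflow: the
sample-size formula (with an iterated small-sample t correction) used to
decide how many random quadrat frames a plot needs, pairwise-Pearson
collinearity screening with the retention preferences used throughout the
density and survival analyses, and the cross-scale correlation analysis
relating nest-site measurements to plot averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, special

__all__ = [
    "ScreenResult",
    "required_sample_size",
    "collinearity_screen",
    "cross_scale_correlation",
    "DEFAULT_PRIORITY",
    "DEFAULT_EXCLUSIVE_PAIRS",
]

#: Default retention order under collinearity, highest priority first:
#: biomass over its structural proxies (VOR, grass heights), shrub cover
#: over shrub height, litter cover over bare ground.
DEFAULT_PRIORITY = [
    "biomass",
    "shrub_cover",
    "litter_cover",
    "forb_cover",
    "residual_grass_cover",
    "slope",
    "biomass_sd",
    "exotic_grass_cover",
    "vor",
    "live_grass_height",
    "residual_grass_height",
    "shrub_height",
    "bare_ground_cover",
]

#: Pairs kept in the analysis but never allowed in the same model.
DEFAULT_EXCLUSIVE_PAIRS = [("biomass", "exotic_grass_cover")]


def required_sample_size(mean: float, sd: float, precision: float = 0.15,
                         z: float = 1.64, max_iter: int = 50) -> int:
    """Number of samples needed to estimate a mean to a target precision.

    The uncorrected size is n = z^2 s^2 / B^2 with B = mean * precision
    (z = 1.64 for a 90% confidence interval).  Because n itself sets the
    degrees of freedom, the small-sample correction replaces z with the t
    quantile at the current n and iterates until the integer ceiling
    stabilizes (on a cycle, the larger — conservative — value is kept).
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return 1
    B = mean * precision
    tail = stats.norm.cdf(z)  # one-sided level implied by the supplied z
    ratio = sd ** 2 / B ** 2
    # smallest n >= 2 satisfying its own t-based requirement:
    # n >= t(n-1)^2 s^2 / B^2.  This is the fixed point the naive
    # back-substitution oscillates around, approached from below so the
    # result is deterministic and monotone in s and 1/B.
    n = max(math.ceil(z ** 2 * ratio), 2)
    for _ in range(max_iter * 100):
        need = stats.t.ppf(tail, df=n - 1) ** 2 * ratio
        if n >= need:
            return n
        n += 1
    return n


@dataclass
class ScreenResult:
    correlation: pd.DataFrame
    retained: list = field(default_factory=list)
    removed: list = field(default_factory=list)          # (covariate, partner, r)
    mutually_exclusive: list = field(default_factory=list)  # (a, b, r)
    threshold: float = 0.6

    def log_lines(self) -> list:
        lines = [f"collinearity screen, |r| >= {self.threshold}"]
        for cov, partner, r in self.removed:
            lines.append(f"removed {cov}: r = {r:+.2f} with {partner}")
        for a, b, r in self.mutually_exclusive:
            lines.append(f"{a} and {b} retained but never co-modeled (r = {r:+.2f})")
        return lines


def collinearity_screen(table: pd.DataFrame, threshold: float = 0.6,
                        priority: list | None = None,
                        exclusive_pairs: list | None = None) -> ScreenResult:
    """Pairwise-Pearson collinearity screen with priority-based removal.

    For every covariate pair with |r| >= ``threshold`` the lower-priority
    member is removed, except for pairs declared mutually exclusive, which
    are both retained but flagged so candidate-model builders keep them
    apart (the biomass / exotic-grass case).
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two covariates to screen")
    priority = list(priority if priority is not None else DEFAULT_PRIORITY)
    exclusive = [tuple(sorted(p)) for p in
                 (exclusive_pairs if exclusive_pairs is not None else DEFAULT_EXCLUSIVE_PAIRS)]
    corr = table.corr(method="pearson")
    cols = list(table.columns)
    removed, exclusive_found = [], []
    retained = list(cols)
    pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    # process the strongest correlations first
    pairs.sort(key=lambda ab: -abs(corr.loc[ab[0], ab[1]]))
    for a, b in pairs:
        r = float(corr.loc[a, b])
        if abs(r) < threshold or a not in retained or b not in retained:
            continue
        if tuple(sorted((a, b))) in exclusive:
            exclusive_found.append((a, b, r))
            continue
        if a not in priority or b not in priority:
            missing = a if a not in priority else b
            raise ValueError(f"correlated covariate {missing!r} absent from the priority list")
        drop = a if priority.index(a) > priority.index(b) else b
        keep = b if drop == a else a
        retained.remove(drop)
        removed.append((drop, keep, r))
    return ScreenResult(corr, retained, removed, exclusive_found, threshold)


def _transform(values: np.ndarray, how: str | None) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if how is None or how == "none":
        return v
    if how == "log":
        if np.any(v <= 0):
            raise ValueError("log transform requires strictly positive values")
        return np.log(v)
    if how == "logit":
        n = v.size
        v = np.clip(v, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))  # nudge exact 0/1
        return special.logit(v)
    raise ValueError(f"unknown transform {how!r}")


def cross_scale_correlation(
    nest_values: pd.DataFrame,
    plot_means: pd.DataFrame,
    transforms: dict | None = None,
    r_threshold: float = 0.6,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Correlate nest-site measurements with their plot-scale averages.

    Both frames are indexed by plot (only plots holding at least one nest
    belong here) and share covariate columns.  Each covariate may be
    transformed first (``"log"`` for strictly positive measures,
    ``"logit"`` for proportions, ``None`` otherwise).  An association is
    ``meaningful`` when |r| > ``r_threshold`` and p < ``p_threshold``.
    """
    common = [c for c in nest_values.columns if c in plot_means.columns]
    if not common:
        raise ValueError("no shared covariate columns")
    transforms = transforms or {}
    rows = []
    aligned = nest_values.join(plot_means, how="inner", lsuffix="_nest", rsuffix="_plot")
    if len(aligned) < 3:
        raise ValueError("need at least 3 paired plots")
    for c in common:
        how = transforms.get(c)
        x = _transform(aligned[f"{c}_nest"].to_numpy(), how)
        y = _transform(aligned[f"{c}_plot"].to_numpy(), how)
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)  # exact t transform, n - 2 df
        rows.append({"covariate": c, "n": len(aligned), "r": r, "p": p,
                     "meaningful": bool(abs(r) > r_threshold and p < p_threshold)
                     if np.isfinite(r) else False})
    return pd.DataFrame(rows).set_index("covariate")
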