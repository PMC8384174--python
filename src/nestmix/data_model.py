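"""Domain types and I/O shared by all analysis stages.

The package analyses replicated nest-search surveys: each 9-ha study plot
is searched 2-3 times within a ~30-day window and the number of active
nests found on each pass is recorded, together with survey conditions
(date, time of day, wind, temperature, cloud) and plot-scale vegetation
covariates (herbaceous biomass, proportional covers, slope).  Individual
nests, once found, are revisited every few days until they fledge or fail,
yielding encounter records for the daily-survival analysis.  Vegetation is
sampled in 20 x 50 cm quadrat frames with ocular cover estimates recorded
in six ordinal percentage bins.

All tabular I/O is comma-separated UTF-8 text with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COVER_BINS",
    "SURVEY_COVARIATES",
    "CountDataset",
    "EncounterRecord",
    "VegetationSample",
    "CalibrationSet",
    "FRAME_AREA_M2",
    "cover_bin_midpoint",
    "calibrate_biomass",
    "standardize",
    "unstandardize",
    "unstandardize_coefficients",
    "read_count_dataset",
    "write_count_dataset",
    "read_encounter_records",
    "write_encounter_records",
    "write_encounter_histories",
    "encounter_records_to_frame",
]

#: Ordinal cover bins used by the quadrat-frame protocol (Daubenmire-style),
#: mapped to their percentage ranges.
COVER_BINS: dict[str, tuple[float, float]] = {
    "0-5": (0.0, 5.0),
    "6-25": (6.0, 25.0),
    "26-50": (26.0, 50.0),
    "51-75": (51.0, 75.0),
    "76-95": (76.0, 95.0),
    "96-100": (96.0, 100.0),
}

#: Per-(plot, occasion) survey condition covariates, in file-column order.
SURVEY_COVARIATES = ("date", "time", "wind", "temp", "cloud")

#: Quadrat frame area: 20 cm x 50 cm = 0.1 m^2.
FRAME_AREA_M2 = 0.1


def _normalize_bin_label(label: str) -> str:
    # accept the typographic en-dash used in field sheets
    return str(label).strip().replace("–", "-").replace("—", "-")


def cover_bin_midpoint(bin_label: str) -> float:
    """Midpoint of an ordinal cover bin, as a proportion in [0, 1].

    >>> cover_bin_midpoint("0-5")
    0.025
    """
    key = _normalize_bin_label(bin_label)
    if key not in COVER_BINS:
        raise ValueError(
            f"unknown cover bin {bin_label!r}; legal bins: {sorted(COVER_BINS)}"
        )
    lo, hi = COVER_BINS[key]
    return (lo + hi) / 2.0 / 100.0


@dataclass
class CountDataset:
    """Replicated nest counts with survey and plot covariates.

    Attributes
    ----------
    plot_ids
        Plot identifiers, length M.
    y
        Integer count matrix, shape (M, T).  Entries at unsurveyed
        occasions are stored as 0 but masked out.
    observed_mask
        Boolean matrix, shape (M, T); True where the occasion was surveyed.
        Missing occasions are never imputed: every likelihood skips them.
    survey_covariates
        Mapping covariate name -> (M, T) float array.
    plot_covariates
        Per-plot covariates, a DataFrame indexed by plot id.
    """

    plot_ids: list
    y: np.ndarray
    observed_mask: np.ndarray
    survey_covariates: dict[str, np.ndarray] = field(default_factory=dict)
    plot_covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        self.validate()

    @property
    def n_plots(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    def validate(self) -> None:
        M, T = self.y.shape
        if len(self.plot_ids) != M:
            raise ValueError("plot_ids length does not match count matrix")
        if self.observed_mask.shape != (M, T):
            raise ValueError("observed_mask shape does not match count matrix")
        obs = self.observed_mask
        y_obs = np.asarray(self.y, dtype=float)[obs]
        if y_obs.size and (np.any(y_obs < 0) or np.any(y_obs != np.floor(y_obs))):
            raise ValueError("counts must be non-negative integers where observed")
        for name, arr in self.survey_covariates.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (M, T):
                raise ValueError(f"survey covariate {name!r} has shape {arr.shape}")
            if np.any(~np.isfinite(arr[obs])):
                raise ValueError(f"survey covariate {name!r} is NaN at a surveyed occasion")
            self.survey_covariates[name] = arr
        if self.plot_covariates is not None:
            missing = set(map(str, self.plot_ids)) - set(map(str, self.plot_covariates.index))
            if missing:
                raise ValueError(f"plot covariates missing for plots: {sorted(missing)}")

    def max_count(self) -> int:
        obs = self.y[self.observed_mask]
        return int(obs.max()) if obs.size else 0


@dataclass
class EncounterRecord:
    """One nest's monitoring interval and fate.

    Days are integers counted from a season origin (day 1 = 1 May).  The
    failure, when it occurs, falls in the half-open interval
    (last_active, last_checked]: the nest was seen active on ``last_active``
    and found failed on ``last_checked``.  Successful nests have
    ``last_active == last_checked`` (survival is modelled through
    ``last_active`` only).
    """

    nest_id: str
    plot_id: str
    first_found: int
    last_active: int
    last_checked: int
    fate: str  # "success" | "failure"
    year: str = "1"
    nest_covariates: dict[str, float] = field(default_factory=dict)
    plot_covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fate not in ("success", "failure"):
            raise ValueError(f"fate must be 'success' or 'failure', got {self.fate!r}")
        if not (self.first_found <= self.last_active <= self.last_checked):
            raise ValueError(
                f"nest {self.nest_id}: require first_found <= last_active <= last_checked"
            )
        if self.fate == "success" and self.last_active != self.last_checked:
            raise ValueError(
                f"nest {self.nest_id}: successful nests must have last_active == last_checked"
            )

    @property
    def exposure_days(self) -> int:
        """Days of known survival (first_found to last_active)."""
        return self.last_active - self.first_found

    @property
    def failure_window(self) -> int:
        """Width of the interval within which a failure occurred (0 for success)."""
        return self.last_checked - self.last_active


@dataclass
class VegetationSample:
    """One quadrat-frame vegetation sample (random point or nest site)."""

    plot_id: str
    location: str  # "random_point" | "nest"
    cover_bins: dict[str, str] = field(default_factory=dict)  # class -> bin label
    heights_cm: dict[str, float] = field(default_factory=dict)
    litter_depth_cm: float = 0.0
    slope_deg: float = 0.0
    biomass_estimated_green_g: float = 0.0
    observer_id: str = ""

    def __post_init__(self) -> None:
        if self.location not in ("random_point", "nest"):
            raise ValueError(f"location must be 'random_point' or 'nest', got {self.location!r}")
        for cls, label in self.cover_bins.items():
            if _normalize_bin_label(label) not in COVER_BINS:
                raise ValueError(f"illegal cover bin {label!r} for class {cls!r}")
        for name, h in self.heights_cm.items():
            if h < 0:
                raise ValueError(f"negative height for {name!r}")
        if self.litter_depth_cm < 0 or self.biomass_estimated_green_g < 0:
            raise ValueError("depths and masses must be non-negative")

    def cover_proportions(self) -> dict[str, float]:
        return {cls: cover_bin_midpoint(lab) for cls, lab in self.cover_bins.items()}


@dataclass
class CalibrationSet:
    """Observer biomass-calibration data.

    ``observer_pairs`` holds (observer_id, estimated_green_g, clipped_green_g)
    from double-sampled frames; ``green_dry_pairs`` holds
    (clipped_green_g, dry_g) from oven-dried clip samples.
    """

    observer_pairs: list[tuple[str, float, float]]
    green_dry_pairs: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for _, est, clip in self.observer_pairs:
            if est < 0 or clip < 0:
                raise ValueError("calibration masses must be non-negative")
        for green, dry in self.green_dry_pairs:
            if green < 0 or dry < 0:
                raise ValueError("calibration masses must be non-negative")

    def observer_offset(self, observer_id: str) -> float:
        """Mean (estimated - clipped) green mass for one observer."""
        diffs = [est - clip for obs, est, clip in self.observer_pairs if obs == observer_id]
        if not diffs:
            raise KeyError(f"observer {observer_id!r} absent from calibration set")
        return float(np.mean(diffs))

    def green_to_dry_offset(self) -> float:
        """Overall mean (green - dry) mass difference."""
        if not self.green_dry_pairs:
            return 0.0
        return float(np.mean([g - d for g, d in self.green_dry_pairs]))


def calibrate_biomass(
    samples: list[VegetationSample], calib: CalibrationSet
) -> pd.DataFrame:
    """Observer-corrected dry biomass per sample, in g/frame and kg/ha.

    Each ocular green-mass estimate is shifted by its observer's mean
    (estimated - clipped) difference, then converted to dry mass by
    subtracting the overall mean (green - dry) difference from the clip
    calibration.  Dry masses are floored at 0 (the additive offsets can go
    negative on small samples).  The 0.1 m^2 frame area converts g/frame to
    kg/ha (1 g/frame = 100 kg/ha).
    """
    dry_offset = calib.green_to_dry_offset()
    rows = []
    for s in samples:
        corrected_green = s.biomass_estimated_green_g - calib.observer_offset(s.observer_id)
        dry = max(corrected_green - dry_offset, 0.0)
        rows.append(
            {
                "plot_id": s.plot_id,
                "location": s.location,
                "observer_id": s.observer_id,
                "green_corrected_g": corrected_green,
                "dry_g": dry,
                "dry_kg_ha": dry / FRAME_AREA_M2 * 10.0,  # g/m^2 -> kg/ha
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariate standardization


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Centre and scale every column to mean 0, sample SD 1.

    Returns the standardized table and a (mean, sd) parameter frame so that
    fitted coefficients can be reported back on the raw measurement scale.
    Constant columns are an error: they carry no contrast and would divide
    by zero.
    """
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=1)
    bad = sds[~(sds > 0)].index.tolist()
    if bad:
        raise ValueError(f"constant column(s) cannot be standardized: {bad}")
    z = (table - means) / sds
    params = pd.DataFrame({"mean": means, "sd": sds})
    return z, params


def unstandardize(z: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`standardize`."""
    return z * params["sd"] + params["mean"]


def unstandardize_coefficients(
    beta: dict[str, float], params: pd.DataFrame
) -> dict[str, float]:
    """Convert slopes fitted on the standardized scale to the raw scale.

    A linear term ``b`` on z = (x - m)/s becomes ``b / s`` per raw unit; a
    quadratic term (entered as ``name^2`` on the squared standardized
    column) becomes ``b / s^2``.  Intercepts are left untouched (they refer
    to covariates at their means either way; reconstituting a raw-scale
    intercept requires the full coefficient vector).
    """
    out = {}
    for name, b in beta.items():
        if name.endswith("^2"):
            base = name[:-2]
            out[name] = b / float(params.loc[base, "sd"]) ** 2 if base in params.index else b
        elif name in params.index:
            out[name] = b / float(params.loc[name, "sd"])
        else:
            out[name] = b
    return out


# ---------------------------------------------------------------------------
# readers / writers


def read_count_dataset(
    counts_path: str | Path,
    survey_cov_path: str | Path | None = None,
    plot_cov_path: str | Path | None = None,
) -> CountDataset:
    """Read a replicated-count dataset from delimited text.

    ``counts_path`` is long format with columns ``plot_id, occasion, count``
    and, optionally, the survey covariates inline; a separate
    ``survey_cov_path`` (same key columns) is merged if given.  Occasions a
    plot was never surveyed on are simply absent from the file and are
    flagged in ``observed_mask`` — they are never imputed.
    """
    counts = pd.read_csv(counts_path)
    required = {"plot_id", "occasion", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts file must contain columns {sorted(required)}")
    if survey_cov_path is not None:
        sc = pd.read_csv(survey_cov_path)
        counts = counts.merge(sc, on=["plot_id", "occasion"], how="left", validate="one_to_one")
    if counts.duplicated(["plot_id", "occasion"]).any():
        dups = counts[counts.duplicated(["plot_id", "occasion"])]
        raise ValueError(f"duplicate (plot, occasion) rows: {dups[['plot_id', 'occasion']].values.tolist()}")
    c = counts["count"].astype(float)
    if (c < 0).any() or (c != np.floor(c)).any():
        raise ValueError("counts must be non-negative integers")

    plot_ids = sorted(counts["plot_id"].astype(str).unique())
    occasions = sorted(counts["occasion"].astype(int).unique())
    occ_index = {o: j for j, o in enumerate(occasions)}
    M, T = len(plot_ids), len(occasions)
    y = np.zeros((M, T), dtype=int)
    mask = np.zeros((M, T), dtype=bool)
    cov_names = [c for c in SURVEY_COVARIATES if c in counts.columns]
    covs = {name: np.full((M, T), np.nan) for name in cov_names}
    pidx = {p: i for i, p in enumerate(plot_ids)}
    for _, row in counts.iterrows():
        i, j = pidx[str(row["plot_id"])], occ_index[int(row["occasion"])]
        y[i, j] = int(row["count"])
        mask[i, j] = True
        for name in cov_names:
            covs[name][i, j] = float(row[name])

    plot_covs = None
    if plot_cov_path is not None:
        plot_covs = pd.read_csv(plot_cov_path).set_index("plot_id")
        plot_covs.index = plot_covs.index.astype(str)
        if set(plot_ids) != set(plot_covs.index):
            raise ValueError("plot ids differ between counts and plot-covariate files")
        plot_covs = plot_covs.loc[plot_ids]
    return CountDataset(plot_ids, y, mask, covs, plot_covs)


def write_count_dataset(data: CountDataset, counts_path: str | Path,
                        plot_cov_path: str | Path | None = None) -> None:
    """Write a CountDataset back to the long-format text layout."""
    rows = []
    for i, pid in enumerate(data.plot_ids):
        for j in range(data.n_occasions):
            if not data.observed_mask[i, j]:
                continue
            row = {"plot_id": pid, "occasion": j + 1, "count": int(data.y[i, j])}
            for name, arr in data.survey_covariates.items():
                row[name] = arr[i, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(counts_path, index=False)
    if plot_cov_path is not None and data.plot_covariates is not None:
        data.plot_covariates.rename_axis("plot_id").to_csv(plot_cov_path)


_RECORD_COLUMNS = ["nest_id", "plot_id", "first_found", "last_active",
                   "last_checked", "fate", "year"]


def encounter_records_to_frame(records: list[EncounterRecord]) -> pd.DataFrame:
    """Flatten encounter records (and their covariates) to one row per nest."""
    rows = []
    for r in records:
        row = {k: getattr(r, k) for k in _RECORD_COLUMNS}
        for k, v in r.nest_covariates.items():
            row[f"nest_{k}"] = v
        for k, v in r.plot_covariates.items():
            row[f"plot_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_encounter_records(records: list[EncounterRecord], path: str | Path) -> None:
    encounter_records_to_frame(records).to_csv(path, index=False)


def read_encounter_records(path: str | Path) -> list[EncounterRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        nest_cov = {c[len("nest_"):]: float(row[c]) for c in df.columns if c.startswith("nest_") and c != "nest_id"}
        plot_cov = {c[len("plot_"):]: float(row[c]) for c in df.columns if c.startswith("plot_") and c != "plot_id"}
        records.append(
            EncounterRecord(
                nest_id=str(row["nest_id"]),
                plot_id=str(row["plot_id"]),
                first_found=int(row["first_found"]),
                last_active=int(row["last_active"]),
                last_checked=int(row["last_checked"]),
                fate=str(row["fate"]),
                year=str(row["year"]),
                nest_covariates=nest_cov,
                plot_covariates=plot_cov,
            )
        )
    return records


def write_encounter_histories(records: list[EncounterRecord], path: str | Path) -> None:
    """Plain-text encounter-history export.

    One whitespace-separated line per nest:
    ``first_found last_active last_checked fate``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"{r.first_found} {r.last_active} {r.last_checked} {r.fate}\n")
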