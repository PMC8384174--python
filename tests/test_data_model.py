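"""Domain types, I/O round-trips, calibration, and standardization."""

import numpy as np
import pandas as pd
import pytest

from nestmix.data_model import (
    CalibrationSet,
    CountDataset,
    EncounterRecord,
    VegetationSample,
    calibrate_biomass,
    cover_bin_midpoint,
    encounter_records_to_frame,
    read_count_dataset,
    read_encounter_records,
    standardize,
    unstandardize,
    write_count_dataset,
    write_encounter_histories,
    write_encounter_records,
)


@pytest.mark.parametrize(
    "label, expected",
    [("0-5", 0.025), ("6-25", 0.155), ("26-50", 0.38), ("51-75", 0.63),
     ("76-95", 0.855), ("96-100", 0.98), ("0–5", 0.025)],
)
def test_cover_bin_midpoints(label, expected):
    assert cover_bin_midpoint(label) == pytest.approx(expected)


def test_cover_bin_rejects_illegal_label():
    with pytest.raises(ValueError, match="unknown cover bin"):
        cover_bin_midpoint("40-60")


class TestCountDataset:
    def test_round_trip_preserves_everything(self, tmp_path):
        y = np.array([[1, 0], [2, 2]])
        mask = np.array([[True, True], [True, False]])
        covs = {"wind": np.array([[3.0, 1.0], [2.0, 0.0]])}
        plot_covs = pd.DataFrame({"biomass": [900.0, 1400.0]},
                                 index=pd.Index(["A", "B"], name="plot_id"))
        data = CountDataset(["A", "B"], y, mask, covs, plot_covs)
        write_count_dataset(data, tmp_path / "c.csv", tmp_path / "p.csv")
        back = read_count_dataset(tmp_path / "c.csv", None, tmp_path / "p.csv")
        np.testing.assert_array_equal(back.y[back.observed_mask], y[mask])
        np.testing.assert_array_equal(back.observed_mask, mask)
        np.testing.assert_allclose(back.survey_covariates["wind"][mask], covs["wind"][mask])
        np.testing.assert_allclose(back.plot_covariates["biomass"], plot_covs["biomass"])

    def test_missing_occasion_is_masked_not_imputed(self, tmp_path):
        pd.DataFrame({"plot_id": ["A", "A", "B"], "occasion": [1, 2, 1],
                      "count": [1, 0, 2]}).to_csv(tmp_path / "c.csv", index=False)
        data = read_count_dataset(tmp_path / "c.csv")
        assert bool(data.observed_mask[1, 1]) is False
        assert data.observed_mask[0].all()

    def test_negative_count_rejected(self, tmp_path):
        pd.DataFrame({"plot_id": ["A"], "occasion": [1], "count": [-1]}
                     ).to_csv(tmp_path / "c.csv", index=False)
        with pytest.raises(ValueError, match="non-negative"):
            read_count_dataset(tmp_path / "c.csv")

    def test_duplicate_rows_rejected(self, tmp_path):
        pd.DataFrame({"plot_id": ["A", "A"], "occasion": [1, 1], "count": [1, 2]}
                     ).to_csv(tmp_path / "c.csv", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_count_dataset(tmp_path / "c.csv")

    def test_mismatched_plot_ids_rejected(self, tmp_path):
        pd.DataFrame({"plot_id": ["A"], "occasion": [1], "count": [1]}
                     ).to_csv(tmp_path / "c.csv", index=False)
        pd.DataFrame({"plot_id": ["Z"], "biomass": [1.0]}
                     ).to_csv(tmp_path / "p.csv", index=False)
        with pytest.raises(ValueError, match="plot ids"):
            read_count_dataset(tmp_path / "c.csv", None, tmp_path / "p.csv")


class TestEncounterRecord:
    def test_interval_ordering_enforced(self):
        with pytest.raises(ValueError, match="first_found"):
            EncounterRecord("n", "p", 10, 8, 12, "failure")

    def test_success_requires_equal_endpoints(self):
        with pytest.raises(ValueError, match="last_active == last_checked"):
            EncounterRecord("n", "p", 1, 5, 8, "success")

    def test_round_trip_and_history_export(self, tmp_path):
        recs = [
            EncounterRecord("n1", "p1", 3, 10, 13, "failure", year="1",
                            plot_covariates={"biomass": 900.0}),
            EncounterRecord("n2", "p1", 5, 34, 34, "success", year="2"),
        ]
        write_encounter_records(recs, tmp_path / "n.csv")
        back = read_encounter_records(tmp_path / "n.csv")
        assert [(r.first_found, r.last_active, r.last_checked, r.fate) for r in back] \
            == [(3, 10, 13, "failure"), (5, 34, 34, "success")]
        assert back[0].plot_covariates["biomass"] == 900.0
        write_encounter_histories(recs, tmp_path / "hist.txt")
        lines = (tmp_path / "hist.txt").read_text().splitlines()
        assert lines[0].split() == ["3", "10", "13", "failure"]


class TestBiomassCalibration:
    def test_zero_offset_calibration_is_identity(self):
        calib = CalibrationSet([("x", 10.0, 10.0), ("x", 7.0, 7.0)],
                               [(10.0, 10.0)])
        s = VegetationSample("A", "random_point", observer_id="x",
                             biomass_estimated_green_g=5.0)
        out = calibrate_biomass([s], calib)
        assert out["dry_g"].iloc[0] == pytest.approx(5.0)
        assert out["dry_kg_ha"].iloc[0] == pytest.approx(500.0)  # 0.1 m^2 frame

    def test_mean_difference_rule_hand_arithmetic(self):
        # observer X over-estimates by 1 g on average; drying loses 3 g on average
        calib = CalibrationSet([("X", 12.0, 10.0), ("X", 8.0, 8.0)],
                               [(10.0, 6.0), (10.0, 8.0)])
        s = VegetationSample("A", "nest", observer_id="X",
                             biomass_estimated_green_g=11.0)
        out = calibrate_biomass([s], calib)
        assert out["green_corrected_g"].iloc[0] == pytest.approx(10.0)
        assert out["dry_g"].iloc[0] == pytest.approx(7.0)

    def test_dry_mass_floored_at_zero(self):
        calib = CalibrationSet([("X", 5.0, 2.0)], [(10.0, 9.0)])
        s = VegetationSample("A", "nest", observer_id="X",
                             biomass_estimated_green_g=1.0)
        assert calibrate_biomass([s], calib)["dry_g"].iloc[0] == 0.0

    def test_unknown_observer_is_an_error(self):
        calib = CalibrationSet([("X", 5.0, 5.0)], [])
        s = VegetationSample("A", "nest", observer_id="Y",
                             biomass_estimated_green_g=1.0)
        with pytest.raises(KeyError, match="Y"):
            calibrate_biomass([s], calib)

    def test_illegal_cover_bin_rejected(self):
        with pytest.raises(ValueError, match="illegal cover bin"):
            VegetationSample("A", "nest", cover_bins={"grass": "10-20"})


class TestStandardize:
    def test_hand_example_sample_sd(self):
        z, params = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z["x"], [-1.0, 0.0, 1.0])
        assert params.loc["x", "mean"] == 2.0
        assert params.loc["x", "sd"] == 1.0

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        z1, _ = standardize(df)
        z2, p2 = standardize(z1)
        np.testing.assert_allclose(z1["x"], z2["x"], atol=1e-12)
        assert p2.loc["x", "mean"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(pd.DataFrame({"x": [5.0, 5.0, 5.0]}))

    def test_unstandardize_round_trips(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(3, 2, 40), "b": rng.uniform(0, 1, 40)})
        z, params = standardize(df)
        np.testing.assert_allclose(unstandardize(z, params), df, atol=1e-12)


def test_records_frame_carries_two_scale_covariates():
    r = EncounterRecord("n1", "p1", 1, 4, 7, "failure",
                        nest_covariates={"forb_cover": 0.1},
                        plot_covariates={"forb_cover": 0.2})
    df = encounter_records_to_frame([r])
    assert df.loc[0, "nest_forb_cover"] == 0.1
    assert df.loc[0, "plot_forb_cover"] == 0.2
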