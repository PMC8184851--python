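"""Synthetic generator: determinism, proportions, generative law, round trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from fragno2.landscape import count_patches
from fragno2.synthetic import (
    ConfigurationError,
    ScenarioConfig,
    deterministic_no2,
    generate_landuse_raster,
    generate_no2_panel,
    generate_scenario,
    read_controls,
    read_panels,
    read_rasters,
    write_scenario,
)


class TestRasterGeneration:
    def test_degenerate_single_class_is_one_patch(self, small_config):
        cfg = dataclasses.replace(
            small_config, class_proportions=(0.0, 1.0, 0.0, 0.0, 0.0, 0.0),
            fragmentation_level=0.0,
        )
        raster = generate_landuse_raster(cfg, station_seed=1)
        assert (raster.grid == 1).all()
        assert count_patches(raster) == 1

    def test_deterministic_given_seed(self, small_config):
        a = generate_landuse_raster(small_config, station_seed=5)
        b = generate_landuse_raster(small_config, station_seed=5)
        assert (a.grid == b.grid).all()
        c = generate_landuse_raster(small_config, station_seed=6)
        assert (a.grid != c.grid).any()

    def test_class_proportions_conserved(self, small_config):
        proportions = (0.3, 0.1, 0.2, 0.1, 0.2, 0.1)
        cfg = dataclasses.replace(small_config, class_proportions=proportions,
                                  raster_rows=64, raster_cols=64)
        raster = generate_landuse_raster(cfg, station_seed=3)
        realised = np.bincount(raster.grid.ravel(), minlength=6) / raster.grid.size
        assert np.abs(realised - np.array(proportions)).max() <= 0.02

    def test_fragmentation_raises_patch_count(self, small_config):
        proportions = (0.3, 0.1, 0.2, 0.1, 0.2, 0.1)
        means = []
        for level in (0.2, 0.8):
            cfg = dataclasses.replace(
                small_config, class_proportions=proportions, raster_rows=64,
                raster_cols=64, fragmentation_level=level,
            )
            counts = [count_patches(generate_landuse_raster(cfg, s)) for s in range(50)]
            means.append(np.mean(counts))
        assert means[1] > means[0]

    def test_invalid_proportions_rejected(self, small_config):
        with pytest.raises(ConfigurationError):
            dataclasses.replace(small_config, class_proportions=(0.5, 0.5, 0.5, 0, 0, 0))


class TestPanelGeneration:
    def _profiles(self, config, k=4):
        from fragno2.landscape import fragmentation_profile

        center = (config.raster_rows // 2, config.raster_cols // 2)
        return [
            fragmentation_profile(generate_landuse_raster(config, s), center,
                                  config.buffer_radius)
            for s in range(k)
        ]

    def test_null_scenario_has_identical_law_before_and_after(self, small_config):
        cfg = dataclasses.replace(small_config, suppression_base=0.0,
                                  suppression_betas=(0.0,) * 6, noise_sd=0.0,
                                  ar_coefficient=0.0, met_effect_coeffs=(0, 0, 0))
        profiles = self._profiles(cfg, 2)
        panels, truth = generate_no2_panel(cfg, profiles, seed=1)
        assert np.all(truth["s_during"] == 0.0)
        expected = deterministic_no2(cfg, np.arange(len(panels[0].dates), dtype=float))
        for panel in panels:
            np.testing.assert_allclose(panel.no2_observed, expected, atol=1e-12)

    def test_noiseless_limit_is_exact_seasonal_curve(self, small_config):
        cfg = dataclasses.replace(small_config, noise_sd=0.0, ar_coefficient=0.0,
                                  met_effect_coeffs=(0.0, 0.0, 0.0),
                                  suppression_base=0.0)
        profiles = self._profiles(cfg, 1)
        panels, _ = generate_no2_panel(cfg, profiles, seed=2)
        day = np.arange(len(panels[0].dates), dtype=float)
        np.testing.assert_allclose(panels[0].no2_observed, deterministic_no2(cfg, day),
                                   atol=1e-12)

    def test_mean_suppression_ratio_matches_base(self, small_config):
        """With flat betas, mean observed/counterfactual after lockdown ~ 0.7."""
        cfg = dataclasses.replace(small_config, suppression_base=0.3,
                                  suppression_betas=(0.0,) * 6, n_stations=20)
        profiles = self._profiles(cfg, 20)
        ratios = []
        for seed in range(5):
            panels, truth = generate_no2_panel(cfg, profiles, seed=seed)
            lockdown = pd.Timestamp(cfg.lockdown_date)
            for i, panel in enumerate(panels):
                during = np.asarray(panel.dates >= lockdown)
                unsuppressed = truth["mean_paths"][i][during]
                ratios.append(panel.no2_observed[during].mean() / unsuppressed.mean())
        assert np.mean(ratios) == pytest.approx(0.7, abs=0.03)

    def test_empty_profiles_rejected(self, small_config):
        with pytest.raises(ValueError):
            generate_no2_panel(small_config, [], seed=0)


class TestDownstreamNullBehaviour:
    """Generator-level properties checked through the DTW stage, using the
    known unsuppressed mean path as the counterfactual (no forecasting)."""

    @staticmethod
    def _dtw_scores(cfg, seeds):
        from fragno2.dtw import score_variation
        from fragno2.forecast import ForecastResult, SarimaxOrder

        before, during = [], []
        for seed in seeds:
            scenario = generate_scenario(dataclasses.replace(cfg, seed=seed))
            for panel in scenario.panels:
                mean_path = scenario.counterfactual[panel.station_id]
                sel = panel.dates >= pd.Timestamp(cfg.forecast_start)
                fc = ForecastResult(
                    station_id=panel.station_id,
                    forecast_dates=panel.dates[sel],
                    no2_predicted=mean_path[np.asarray(sel)],
                    sd1_lower=mean_path[np.asarray(sel)],
                    sd1_upper=mean_path[np.asarray(sel)],
                    sd2_lower=mean_path[np.asarray(sel)],
                    sd2_upper=mean_path[np.asarray(sel)],
                    chosen_order=SarimaxOrder(0, 0, 0),
                    aic=0.0, ljung_box_p=0.5, jarque_bera_p=0.5,
                )
                res = score_variation(panel, fc, cfg.lockdown_date)
                before.append(res.dtw_before)
                during.append(res.dtw_during)
        return np.array(before), np.array(during)

    def test_null_scenario_windows_indistinguishable(self, small_config):
        """Without suppression, variation scores over equal-length windows
        before and during the nominal lockdown come from the same
        distribution."""
        from scipy import stats

        cfg = dataclasses.replace(
            small_config, n_stations=10, suppression_base=0.0,
            suppression_betas=(0.0,) * 6,
            forecast_start="2020-01-01", lockdown_date="2020-03-02",
            end_date="2020-05-01",  # 61-day windows on both sides
        )
        before, during = self._dtw_scores(cfg, seeds=range(5))
        assert stats.mannwhitneyu(before, during).pvalue > 0.01

    def test_stronger_suppression_gives_stochastically_larger_scores(self, small_config):
        during = {}
        for base in (0.1, 0.3):
            cfg = dataclasses.replace(small_config, n_stations=10, suppression_base=base)
            _, during[base] = self._dtw_scores(cfg, seeds=range(3))
        from scipy import stats

        test = stats.mannwhitneyu(during[0.3], during[0.1], alternative="greater")
        assert test.pvalue < 0.01
        assert np.median(during[0.3]) > np.median(during[0.1])


class TestScenarioBundle:
    def test_minimal_scenario(self):
        cfg = ScenarioConfig(n_stations=1, history_start="2019-01-01",
                             raster_rows=16, raster_cols=16, seed=1)
        scenario = generate_scenario(cfg)
        assert len(scenario.panels) == 1
        assert len(scenario.rasters) == 1
        assert len(scenario.controls) == 1
        assert scenario.station_ids == ["S001"]

    def test_bundle_station_ids_consistent(self, small_config):
        scenario = generate_scenario(small_config)
        ids = set(scenario.station_ids)
        assert {p.station_id for p in scenario.panels} == ids
        assert set(scenario.rasters) == ids
        assert set(scenario.controls["station_id"]) == ids
        assert set(scenario.suppression["station_id"]) == ids

    def test_byte_identical_outputs_across_runs(self, small_config, tmp_path):
        for sub in ("a", "b"):
            write_scenario(generate_scenario(small_config), tmp_path / sub)
        for name in ("panels.csv", "controls.csv", "ground_truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_round_trip_preserves_numeric_fields(self, small_config, tmp_path):
        scenario = generate_scenario(small_config)
        write_scenario(scenario, tmp_path)
        panels = read_panels(tmp_path / "panels.csv")
        assert len(panels) == len(scenario.panels)
        orig = {p.station_id: p for p in scenario.panels}
        for panel in panels:
            src = orig[panel.station_id]
            np.testing.assert_allclose(panel.no2_observed, src.no2_observed, atol=1e-9)
            np.testing.assert_allclose(panel.temperature, src.temperature, atol=1e-9)
        controls = read_controls(tmp_path / "controls.csv")
        np.testing.assert_allclose(
            controls.drop(columns="station_id").to_numpy(),
            scenario.controls.drop(columns="station_id").to_numpy(), atol=1e-9,
        )
        rasters = read_rasters(tmp_path / "rasters")
        for sid, raster in rasters.items():
            assert (raster.grid == scenario.rasters[sid].grid).all()

    def test_missing_path_raises_with_path_in_message(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope"):
            read_panels(tmp_path / "nope.csv")

    def test_config_date_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(history_start="2020-02-01")
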