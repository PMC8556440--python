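import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from renalpet.cli import main as cli_main
from renalpet.study import (
    StudyConfig,
    expected_series_count,
    load_table2_fixture,
    run_study,
    simulate_null_lru_table,
    table2_aggregates,
)


def small_config(**overrides):
    """Cut-down study for fast end-to-end checks: 3 patients, 8 mm voxels."""
    defaults = dict(n_patients=3, voxel_size=8.0, master_seed=77,
                    extreme_split_patient_ids=(), missing_rebins=())
    defaults.update(overrides)
    return StudyConfig(**defaults)


@pytest.fixture(scope="module")
def small_result():
    return run_study(small_config())


class TestStudyConfig:
    def test_defaults_describe_the_protocol_grid(self):
        cfg = StudyConfig()
        assert cfg.n_patients == 12
        assert cfg.time_points_pi == (5, 12, 20, 30, 60, 120, 210, 330)
        assert cfg.native_durations == (30, 30, 30, 30, 120, 120, 120, 180)
        assert cfg.rebin_durations[-1] == (10, 20, 30, 60, 90, 120)

    def test_expected_series_count_default_grid(self):
        # 12 patients x 31 series, minus 2 patients' lost 2 h rebins (5 each)
        assert expected_series_count(StudyConfig()) == 362

    def test_validation_rejects_bad_grids(self):
        with pytest.raises(ValueError, match="increasing"):
            StudyConfig(time_points_pi=(5, 5, 20, 30, 60, 120, 210, 330))
        with pytest.raises(ValueError, match="rebin"):
            StudyConfig(
                rebin_durations=((), (), (), (40,), (10, 20, 30, 60, 90),
                                 (10, 20, 30, 60, 90), (10, 20, 30, 60, 90),
                                 (10, 20, 30, 60, 90, 120))
            )

    def test_roundtrip_through_dict(self):
        cfg = StudyConfig()
        assert StudyConfig.from_dict(cfg.to_dict()) == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            StudyConfig.from_dict({"n_patient": 5})

    def test_early_scans_share_the_half_hour_mask_group(self):
        cfg = StudyConfig()
        groups = [cfg.mask_group(i) for i in range(8)]
        assert groups == [3, 3, 3, 3, 4, 5, 6, 7]


class TestRunStudy:
    def test_series_count_matches_combinatorial_expectation(self, small_result):
        assert small_result.n_series == expected_series_count(small_result.config)

    def test_rerun_is_bit_identical(self, small_result):
        again = run_study(small_config())
        pd.testing.assert_frame_equal(small_result.lru_table, again.lru_table)
        pd.testing.assert_frame_equal(small_result.noise_cv, again.noise_cv)

    def test_different_seed_changes_measurements(self, small_result):
        other = run_study(small_config(master_seed=78))
        assert not np.allclose(
            small_result.lru_table["lru_percent"], other.lru_table["lru_percent"]
        )

    def test_noise_free_limit_has_vanishing_delta_max(self):
        """With expected counts used directly and no segmentation noise, LRU%
        is constant across the grid (split 0.5, so the intrarenal blood
        compartment, which is symmetric, cannot move the ratio over time);
        residual differences come only from blur/discretization."""
        cfg = small_config(n_patients=2, poisson_noise=False,
                          segmentation_noise_mm=0.0,
                          split_mean=0.5, split_sd=0.0)
        res = run_study(cfg)
        assert (res.summaries["delta_max"] < 0.01).all()

    def test_noise_free_asymmetric_split_constant_within_time_point(self):
        """Without noise, rebinned durations of one acquisition give
        identical LRU%; only the time axis moves it (blood kinetics)."""
        cfg = small_config(n_patients=1, poisson_noise=False,
                          segmentation_noise_mm=0.0)
        res = run_study(cfg)
        spread = res.lru_table.groupby(["patient_id", "time_pi"])[
            "lru_percent"
        ].agg(lambda v: v.max() - v.min())
        assert (spread < 1e-9).all()

    def test_missing_rebins_drop_exactly_their_children(self):
        base = small_config(n_patients=2)
        lost = small_config(n_patients=2, missing_rebins=((1, 120),))
        res_base, res_lost = run_study(base), run_study(lost)
        assert res_base.n_series - res_lost.n_series == 5
        dropped = res_base.lru_table.merge(
            res_lost.lru_table[["patient_id", "time_pi", "duration"]],
            on=["patient_id", "time_pi", "duration"],
            how="left",
            indicator=True,
        )
        gone = dropped[dropped["_merge"] == "left_only"]
        assert set(gone["patient_id"]) == {1}
        assert set(gone["time_pi"]) == {120.0}
        assert set(gone["duration"]) == {10.0, 20.0, 30.0, 60.0, 90.0}

    def test_lru_bounded_and_finite(self, small_result):
        lru = small_result.lru_table["lru_percent"]
        assert ((lru >= 0) & (lru <= 100)).all()

    def test_outputs_written(self, small_result, tmp_path):
        small_result.write(tmp_path)
        for name in (
            "lru_table.csv",
            "patient_summaries.csv",
            "stats_report.json",
            "dose_budget.json",
            "study_config.yaml",
            "peak_times.csv",
        ):
            assert (tmp_path / name).exists()
        report = json.loads((tmp_path / "stats_report.json").read_text())
        assert "kruskal_wallis" in report

    def test_stats_report_attached(self, small_result):
        kw = small_result.stats_report["kruskal_wallis"]["normalized"]
        assert 0 <= kw["time_pi"].raw_p <= 1


class TestNullCohortSimulator:
    def test_balanced_grid_shape(self, rng):
        df = simulate_null_lru_table(n_patients=4, n_time_points=3,
                                     n_durations=2, rng=rng)
        assert len(df) == 4 * 3 * 2
        assert df.groupby("time_pi").size().nunique() == 1

    def test_injected_shift_moves_late_time_points(self, rng):
        df = simulate_null_lru_table(time_shift_pp={7: -5.0}, rng=rng)
        late = df[df["time_pi"] == 7.0]["lru_percent"].mean()
        early = df[df["time_pi"] == 0.0]["lru_percent"].mean()
        assert late < early - 3.0


class TestTable2Fixture:
    def test_row_patient_3(self):
        df = load_table2_fixture().set_index("patient_id")
        row = df.loc[3]
        assert row["median_lru"] == 54.8
        assert (row["range_min"], row["range_max"]) == (53.5, 55.4)
        assert row["delta_max"] == 1.9

    def test_row_patient_8_extreme_split(self):
        row = load_table2_fixture().set_index("patient_id").loc[8]
        assert row["median_lru"] == 5.8
        assert row["delta_max"] == 6.1

    def test_aggregates(self):
        agg = table2_aggregates()
        assert (agg["delta_max_min"], agg["delta_max_max"]) == (1.8, 7.3)
        assert (agg["lru_min"], agg["lru_max"]) == (4.9, 55.4)

    def test_checksum_guard(self, monkeypatch):
        import renalpet.study as study_mod

        monkeypatch.setattr(study_mod, "TABLE2_SHA256", "0" * 64)
        with pytest.raises(ValueError, match="checksum"):
            load_table2_fixture()


class TestCli:
    def test_dose_subcommand_prints_budget(self):
        result = CliRunner().invoke(cli_main, ["dose"])
        assert result.exit_code == 0
        assert "total effective dose: 0.4 mSv" in result.output

    def test_dose_json_output(self):
        result = CliRunner().invoke(cli_main, ["dose", "--json"])
        assert result.exit_code == 0
        assert json.loads(result.output)["conversion_factor"] == pytest.approx(
            4.9167, abs=1e-3
        )

    def test_fixtures_subcommand(self, tmp_path):
        result = CliRunner().invoke(cli_main, ["fixtures", "--outdir", str(tmp_path)])
        assert result.exit_code == 0
        assert (tmp_path / "table2_lru.csv").exists()

    def test_stats_subcommand(self, tmp_path, rng):
        table = simulate_null_lru_table(n_patients=4, rng=rng)
        path = tmp_path / "lru.csv"
        table.to_csv(path, index=False)
        result = CliRunner().invoke(cli_main, ["stats", "--input", str(path)])
        assert result.exit_code == 0
        assert "kruskal_wallis" in result.output

    def test_simulate_and_quantify_roundtrip(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["simulate", "--seed", "1", "--outdir", str(tmp_path),
             "--voxel-size", "8.0"],
        )
        assert result.exit_code == 0, result.output
        result = runner.invoke(
            cli_main,
            ["quantify", "--frame", str(tmp_path / "frame.nii.gz"),
             "--left-mask", str(tmp_path / "mask_left.nii.gz"),
             "--right-mask", str(tmp_path / "mask_right.nii.gz")],
        )
        assert result.exit_code == 0, result.output
        out = json.loads(result.output)
        assert 40.0 < out["lru_percent"] < 55.0

    def test_run_study_subcommand(self, tmp_path):
        cfg = small_config(n_patients=2)
        cfg_path = tmp_path / "config.yaml"
        from renalpet.io import dump_config

        dump_config(cfg.to_dict(), cfg_path)
        result = CliRunner().invoke(
            cli_main,
            ["run-study", "--config", str(cfg_path), "--outdir",
             str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "lru_table.csv").exists()
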