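"""Study orchestration: grids, seeds, outputs, subsetting, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from ddm_recovery import (DiffusionParams, StudyConfig, TrialData,
                          run_recovery_study, run_retest_simulation,
                          simulate_trials, subset_first_n, write_trials)
from ddm_recovery.cli import main as cli_main
from ddm_recovery.study import cell_seed


def tiny_config(**overrides) -> StudyConfig:
    base = dict(design="one_drift", population="study1", n_parameter_sets=3,
                trial_numbers=(48,), contamination=("none",), criteria=("ml",),
                models=(4,), seed=77,
                fitter_options={"n_restarts": 1, "maxfev_factor": 60})
    base.update(overrides)
    return StudyConfig(**base)


class TestSeeds:
    def test_cell_seeds_distinct_and_stable(self):
        s1 = cell_seed(1, "sim", 0, 48).generate_state(2)
        s2 = cell_seed(1, "sim", 0, 48).generate_state(2)
        s3 = cell_seed(1, "sim", 1, 48).generate_state(2)
        np.testing.assert_array_equal(s1, s2)
        assert not np.array_equal(s1, s3)


class TestRecoveryStudy:
    def test_single_cell_yields_single_record(self):
        out = run_recovery_study(tiny_config(n_parameter_sets=1))
        assert len(out["records"]) == 1

    def test_dataset_grid_counts(self):
        """Three contamination conditions x seven trial numbers = 21
        datasets per parameter set."""
        cfg = tiny_config(n_parameter_sets=1,
                          trial_numbers=(24, 32, 40, 48, 56, 64, 72),
                          contamination=("none", "fast", "slow"))
        out = run_recovery_study(cfg)
        cells = out["records"].groupby(["n_trials", "contamination"]).size()
        assert len(cells) == 21
        assert (cells == 1).all()

    def test_rerun_same_seed_byte_identical(self, tmp_path):
        cfg1 = tiny_config(n_parameter_sets=2, output_dir=str(tmp_path / "r1"))
        cfg2 = tiny_config(n_parameter_sets=2, output_dir=str(tmp_path / "r2"))
        run_recovery_study(cfg1)
        run_recovery_study(cfg2)
        b1 = (tmp_path / "r1" / "records.csv").read_bytes()
        b2 = (tmp_path / "r2" / "records.csv").read_bytes()
        assert b1 == b2

    def test_outputs_and_manifest(self, tmp_path):
        cfg = tiny_config(models=(4, 5), min_frac=0.0,
                          output_dir=str(tmp_path / "out"))
        out = run_recovery_study(cfg)
        assert (tmp_path / "out" / "records.csv").exists()
        assert (tmp_path / "out" / "summary.csv").exists()
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["config_hash"] == cfg.config_hash()
        assert manifest["n_records"] == len(out["records"])
        # summary has per-parameter and "mean" rows for each cell
        summary = out["summary"]
        assert set(summary["parameter"]) == {"a", "v", "t0", "zr", "mean"}

    def test_true_and_estimated_columns_present(self):
        out = run_recovery_study(tiny_config())
        rec = out["records"]
        for col in ("true_a", "est_a", "true_v_total", "est_v_total",
                    "filter_pass", "converged"):
            assert col in rec.columns

    def test_yaml_round_trip(self, tmp_path):
        cfg = tiny_config()
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({
            "design": cfg.design, "population": cfg.population,
            "n_parameter_sets": cfg.n_parameter_sets,
            "trial_numbers": list(cfg.trial_numbers),
            "criteria": list(cfg.criteria), "models": list(cfg.models),
            "seed": cfg.seed}))
        loaded = StudyConfig.from_yaml(path)
        assert loaded.trial_numbers == cfg.trial_numbers
        assert loaded.seed == cfg.seed
        with pytest.raises(ValueError):
            path.write_text("bogus_key: 1")
            StudyConfig.from_yaml(path)


class TestRetestSimulation:
    def test_identical_parameter_sessions_structure(self):
        cfg = tiny_config(design="two_drift", population="study2_rmt",
                          n_parameter_sets=4, trial_numbers=(48,),
                          models=(4,))
        out = run_retest_simulation(cfg)
        rel = out["reliability"]
        assert len(rel) == 1
        assert {"a", "v", "t0", "zr", "mean_retest_reliability"} <= set(rel.columns)
        # two sessions per subject per cell
        assert len(out["records"]) == 2 * 4

    def test_rejects_uniform_population(self):
        with pytest.raises(ValueError):
            run_retest_simulation(tiny_config(population="study1"))


class TestSubsetFirstN:
    def test_identity_and_order(self):
        d = TrialData(np.array([0, 1, 1, 0]), np.array([0.4, 0.5, 0.6, 0.7]))
        same = subset_first_n(d, 4)
        np.testing.assert_array_equal(same.rt, d.rt)
        head = subset_first_n(d, 2)
        np.testing.assert_array_equal(head.rt, [0.4, 0.5])
        np.testing.assert_array_equal(head.response, [0, 1])

    def test_bounds_enforced(self):
        d = TrialData(np.array([0, 1]), np.array([0.4, 0.5]))
        with pytest.raises(ValueError):
            subset_first_n(d, 0)
        with pytest.raises(ValueError):
            subset_first_n(d, 3)


class TestCli:
    def test_fit_command(self, tmp_path):
        p = DiffusionParams(1.1, 1.5, 0.3, 0.5)
        d = simulate_trials(p, 80, seed=3)
        path = tmp_path / "trials.dat"
        write_trials(d, path)
        runner = CliRunner()
        result = runner.invoke(cli_main, ["fit", "--data", str(path),
                                          "--model", "4", "--criterion", "ml",
                                          "--seed", "1"])
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert payload["params"]["a"] > 0
        assert payload["criterion"] == "ml"

    def test_run_study_command(self, tmp_path):
        cfg = {"design": "one_drift", "population": "study1",
               "n_parameter_sets": 1, "trial_numbers": [48],
               "contamination": ["none"], "criteria": ["ml"], "models": [4],
               "seed": 5, "output_dir": str(tmp_path / "out"),
               "fitter_options": {"n_restarts": 1, "maxfev_factor": 60}}
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        runner = CliRunner()
        result = runner.invoke(cli_main, ["run-study", "--config", str(cfg_path),
                                          "--no-progress"])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "manifest.json").exists()
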