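"""Parameter populations, trial simulation, contamination, filter, file IO."""

import numpy as np
import pytest

from ddm_recovery import (DiffusionParams, ParameterPopulation,
                          PopulationSpecError, TrialData, draw_parameter_sets,
                          inject_fast_contaminants, inject_slow_contaminants,
                          read_trials, response_probability, simulate_trials,
                          study1_population, study2_population,
                          threshold_balance_filter, write_trials)
from ddm_recovery.simulate import FLAG_FAST, FLAG_NONE, FLAG_SLOW


class TestPopulations:
    def test_degenerate_ranges_give_identical_sets(self):
        spec = (("a", ("uniform", 1.0, 1.0)), ("v", ("uniform", 2.0, 2.0)),
                ("t0", ("uniform", 0.3, 0.3)), ("zr", ("uniform", 0.5, 0.5)),
                ("sv", ("uniform", 0.0, 0.0)), ("st0", ("uniform", 0.0, 0.0)),
                ("szr", ("uniform", 0.0, 0.0)))
        sets = draw_parameter_sets(ParameterPopulation("one_drift", spec), 5, seed=0)
        assert all(p == DiffusionParams(1.0, 2.0, 0.3, 0.5) for p in sets)

    def test_uniform_draws_respect_ranges(self):
        sets = draw_parameter_sets(study1_population(), 3000, seed=1)
        a = np.array([p.a for p in sets])
        v = np.array([p.v for p in sets])
        assert a.min() >= 0.5 and a.max() <= 2.0
        assert v.min() >= -4.0 and v.max() <= 4.0
        assert all(p.t_min >= 0 for p in sets)

    def test_two_drift_population_signs(self):
        sets = draw_parameter_sets(study1_population("two_drift"), 500, seed=2)
        v0 = np.array([p.v for p in sets])
        v1 = np.array([p.v1 for p in sets])
        assert np.mean(v0) < -2.0 and np.mean(v1) > 1.6  # normal means -2.35 / 2.0
        assert all(p.is_two_drift for p in sets)

    def test_normal_draws_are_redrawn_into_domain(self):
        sets = draw_parameter_sets(study2_population("rmt"), 400, seed=3)
        assert all(p.szr >= 0 and p.sv >= 0 and p.t_min >= 0 for p in sets)
        assert all(0 < p.zr - p.szr / 2 and p.zr + p.szr / 2 < 1 for p in sets)

    def test_infeasible_uniform_spec_rejected(self):
        spec = (("a", ("uniform", 0.5, 2.0)), ("v", ("uniform", -4.0, 4.0)),
                ("t0", ("uniform", 0.2, 0.5)), ("zr", ("uniform", 0.1, 0.7)),
                ("sv", ("uniform", 0.0, 1.0)), ("st0", ("uniform", 0.0, 0.2)),
                ("szr", ("uniform", 0.0, 0.5)))  # zr 0.1 with szr up to 0.5
        with pytest.raises(PopulationSpecError):
            ParameterPopulation("one_drift", spec)

    def test_reproducible_under_seed(self):
        s1 = draw_parameter_sets(study1_population(), 10, seed=42)
        s2 = draw_parameter_sets(study1_population(), 10, seed=42)
        assert s1 == s2


class TestSimulateTrials:
    def test_counts_and_support(self, p_full):
        d = simulate_trials(p_full, 200, seed=0)
        assert d.n == 200
        assert np.all(d.rt > p_full.t_min)
        assert np.all(d.flag == FLAG_NONE)

    def test_driftless_symmetric_upper_share(self):
        p = DiffusionParams(1.0, 0.0, 0.3, 0.5)
        d = simulate_trials(p, 40000, seed=5)
        se = 0.5 / np.sqrt(d.n)
        assert abs(d.response.mean() - 0.5) < 3 * se

    def test_upper_share_matches_closed_form(self, p_basic):
        d = simulate_trials(p_basic, 100000, seed=6)
        p_up = response_probability(p_basic, "upper")
        se = np.sqrt(p_up * (1 - p_up) / d.n)
        assert abs(d.response.mean() - p_up) < 3 * se

    def test_two_drift_interleaves_stimuli(self):
        p = DiffusionParams(1.2, -2.3, 0.3, 0.5, v1=2.0)
        d = simulate_trials(p, 101, seed=7)
        assert d.stimulus is not None
        assert np.sum(d.stimulus == 0) == 51  # odd trial goes to stimulus 0
        np.testing.assert_array_equal(d.stimulus[:4], [0, 1, 0, 1])
        # upper responses should dominate for the positive-drift stimulus
        assert d.response[d.stimulus == 1].mean() > d.response[d.stimulus == 0].mean()

    def test_seeded_runs_bit_reproducible(self, p_full):
        d1 = simulate_trials(p_full, 100, seed=9)
        d2 = simulate_trials(p_full, 100, seed=9)
        np.testing.assert_array_equal(d1.rt, d2.rt)
        np.testing.assert_array_equal(d1.response, d2.response)

    def test_invalid_trial_count(self, p_full):
        with pytest.raises(ValueError):
            simulate_trials(p_full, 0, seed=1)


class TestContamination:
    def test_zero_rate_is_identity(self, trials_full, p_full):
        out = inject_fast_contaminants(trials_full, p_full, rate=0.0, seed=0)
        np.testing.assert_array_equal(out.rt, trials_full.rt)
        out = inject_slow_contaminants(trials_full, rate=0.0, seed=0)
        np.testing.assert_array_equal(out.rt, trials_full.rt)

    def test_fast_counts_and_range(self, p_full):
        d = simulate_trials(p_full, 200, seed=1)
        out = inject_fast_contaminants(d, p_full, rate=0.04, seed=2)
        assert int(np.sum(out.flag == FLAG_FAST)) == 8  # round(0.04 * 200)
        t_min = p_full.t_min
        sel = out.rt[out.flag == FLAG_FAST]
        assert np.all(sel >= max(0.0, t_min - 0.1)) and np.all(sel <= t_min + 0.1)
        assert out.n == d.n
        untouched = out.flag == FLAG_NONE
        np.testing.assert_array_equal(out.rt[untouched], d.rt[untouched])

    def test_slow_counts_range_and_responses(self, p_full):
        d = simulate_trials(p_full, 100, seed=3)
        q1, q3 = np.quantile(d.rt, [0.25, 0.75])
        iqr = q3 - q1
        out = inject_slow_contaminants(d, rate=0.04, seed=4)
        sel = out.flag == FLAG_SLOW
        assert int(sel.sum()) == 4
        assert np.all(out.rt[sel] >= q3 + 1.5 * iqr)
        assert np.all(out.rt[sel] <= q3 + 5.0 * iqr)
        np.testing.assert_array_equal(out.response, d.response)  # only RTs replaced

    def test_degenerate_iqr_warns(self):
        d = TrialData(np.array([0, 1, 0, 1, 1]), np.full(5, 0.4))
        with pytest.warns(UserWarning):
            inject_slow_contaminants(d, rate=0.2, seed=0)


class TestThresholdBalanceFilter:
    def test_balanced_passes(self):
        d = TrialData(np.r_[np.zeros(50), np.ones(50)], np.full(100, 0.5))
        assert threshold_balance_filter(d)

    def test_sparse_category_fails(self):
        d = TrialData(np.r_[np.zeros(3), np.ones(97)], np.full(100, 0.5))
        assert not threshold_balance_filter(d)

    def test_zero_threshold_always_passes(self):
        d = TrialData(np.ones(50), np.full(50, 0.5))
        assert threshold_balance_filter(d, min_frac=0.0)


class TestTrialFileIO:
    def test_round_trip_basic_and_extended(self, tmp_path, p_full):
        d = simulate_trials(p_full, 50, seed=8)
        d = inject_fast_contaminants(d, p_full, 0.04, seed=9)
        basic, ext = tmp_path / "b.dat", tmp_path / "e.dat"
        write_trials(d, basic)
        write_trials(d, ext, extended=True)
        back = read_trials(basic)
        np.testing.assert_array_equal(back.response, d.response)
        np.testing.assert_allclose(back.rt, d.rt, atol=1e-6)
        back_ext = read_trials(ext)
        np.testing.assert_array_equal(back_ext.flag, d.flag)

    def test_two_drift_round_trip_keeps_stimulus(self, tmp_path):
        p = DiffusionParams(1.2, -2.3, 0.3, 0.5, v1=2.0)
        d = simulate_trials(p, 30, seed=10)
        path = tmp_path / "t.dat"
        write_trials(d, path, extended=True)
        back = read_trials(path)
        np.testing.assert_array_equal(back.stimulus, d.stimulus)
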