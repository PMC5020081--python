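"""Evaluation formulas: precision, Fisher-Z means, quantiles, superiority,
retest reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ddm_recovery import (DiffusionParams, PrecisionWeights, bias,
                          fisher_z_mean, mean_estimation_precision,
                          model_superiority, parameter_correlations,
                          precision_quantile, retest_reliability)


W_UNIT = PrecisionWeights(a=0.1, v=0.2, t0=0.01, zr=0.02)


class TestMeanEstimationPrecision:
    def test_zero_iff_exact(self):
        t = {"a": 1.0, "v": 2.0, "t0": 0.3, "zr": 0.5}
        assert mean_estimation_precision(t, t, W_UNIT) == 0.0

    def test_unit_when_each_misses_by_its_weight(self):
        t = {"a": 1.0, "v": 2.0, "t0": 0.3, "zr": 0.5}
        e = {"a": 1.1, "v": 2.2, "t0": 0.31, "zr": 0.52}
        assert mean_estimation_precision(e, t, W_UNIT) == pytest.approx(1.0)

    def test_direct_formula_evaluation(self):
        # deviations equal to the weights, one by one: each ratio is 1
        t = {"a": 0, "v": 0, "t0": 0, "zr": 0}
        e = {"a": 0.1, "v": 0.2, "t0": 0.01, "zr": 0.02}
        assert mean_estimation_precision(e, t, W_UNIT) == pytest.approx(1.0)

    def test_missing_parameter_rejected(self):
        with pytest.raises(ValueError):
            mean_estimation_precision({"a": 1.0}, {"a": 1.0}, W_UNIT)

    @given(scale=st.floats(0.1, 10))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_under_joint_rescaling(self, scale):
        t = {"a": 1.0, "v": 2.0, "t0": 0.3, "zr": 0.5}
        e = {"a": 1.2, "v": 1.7, "t0": 0.33, "zr": 0.46}
        w2 = PrecisionWeights(0.1 * scale, 0.2 * scale, 0.01 * scale, 0.02 * scale)
        e2 = {k: t[k] + scale * (e[k] - t[k]) for k in t}
        assert mean_estimation_precision(e2, t, w2) == pytest.approx(
            mean_estimation_precision(e, t, W_UNIT), rel=1e-9)

    def test_weights_must_be_positive(self):
        with pytest.raises(ValueError):
            PrecisionWeights(a=0.0, v=1, t0=1, zr=1)


class TestFisherZMean:
    def test_equal_values_pass_through(self):
        assert fisher_z_mean([0.8, 0.8, 0.8, 0.8]) == pytest.approx(0.8)

    def test_zeros(self):
        assert fisher_z_mean([0, 0, 0, 0]) == 0.0

    def test_hand_checked_value(self):
        # tanh(mean(atanh([0.9, 0.5, 0.7, 0.3])))
        expect = np.tanh(np.mean(np.arctanh([0.9, 0.5, 0.7, 0.3])))
        got = fisher_z_mean([0.9, 0.5, 0.7, 0.3])
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(0.6638, abs=2e-4)

    def test_perfect_correlations_clamped(self):
        assert fisher_z_mean([1.0, 1.0]) == pytest.approx(1.0, abs=1e-9)

    @given(st.lists(st.floats(-0.99, 0.99), min_size=2, max_size=6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_between_min_and_max(self, rs):
        m = fisher_z_mean(rs)
        assert min(rs) - 1e-12 <= m <= max(rs) + 1e-12


class TestQuantiles:
    def test_constant_values(self):
        assert precision_quantile([3.0] * 25) == 3.0

    def test_linear_interpolation_convention(self):
        assert precision_quantile(np.arange(1, 101), q=0.95) == pytest.approx(95.05)

    def test_q_one_is_maximum(self):
        vals = np.random.default_rng(0).random(50)
        assert precision_quantile(vals, q=1.0) == vals.max()

    def test_monotone_in_q(self):
        vals = np.random.default_rng(1).random(60)
        qs = [precision_quantile(vals, q) for q in (0.5, 0.8, 0.95, 1.0)]
        assert qs == sorted(qs)


class TestBiasAndCorrelation:
    def test_bias_zero_when_exact(self):
        ps = [{"a": 1, "v": 2, "t0": 0.3, "zr": 0.5}] * 4
        assert all(v == 0 for v in bias(ps, ps).values())

    def test_bias_arithmetic(self):
        t = [{"a": 1, "v": 2.0, "t0": 0.3, "zr": 0.5},
             {"a": 1, "v": 2.0, "t0": 0.3, "zr": 0.5}]
        e = [{"a": 1.2, "v": 2.1, "t0": 0.3, "zr": 0.5},
             {"a": 0.8, "v": 2.3, "t0": 0.3, "zr": 0.5}]
        b = bias(t, e)
        assert b["a"] == pytest.approx(0.0)
        assert b["v"] == pytest.approx(0.2)

    def test_correlations_drop_zr_for_three_parameter_model(self):
        rng = np.random.default_rng(2)
        t = [{"a": x, "v": y, "t0": z, "zr": 0.5}
             for x, y, z in rng.random((10, 3)) + 0.5]
        c = parameter_correlations(t, t, include_zr=False)
        assert "zr" not in c and c["a"] == pytest.approx(1.0)


class TestModelSuperiority:
    def test_strict_dominance(self):
        df = pd.DataFrame({"model": [3, 4, 5, 7],
                           "corr": [0.5, 0.6, 0.9, 0.7],
                           "bias": [0.3, -0.2, 0.01, 0.1],
                           "precision_q": [5.0, 4.0, 1.0, 2.0]})
        assert model_superiority(df) == "5/5/5"

    def test_mixed_winners_match_hand_ranking(self):
        df = pd.DataFrame({"model": [4, 5, 7],
                           "corr": [0.8, 0.7, 0.6],
                           "bias": [0.2, -0.05, 0.5],
                           "precision_q": [3.0, 2.5, 1.0]})
        assert model_superiority(df) == "4/5/7"

    def test_ties_reported_jointly(self):
        df = pd.DataFrame({"model": [4, 5],
                           "corr": [0.8, 0.8],
                           "bias": [0.1, 0.2],
                           "precision_q": [2.0, 1.0]})
        assert model_superiority(df) == "4,5/4/5"

    def test_three_parameter_model_excluded_for_zr(self):
        df = pd.DataFrame({"model": [3, 4],
                           "corr": [0.99, 0.5],
                           "bias": [0.0, 0.3],
                           "precision_q": [0.1, 3.0]})
        assert model_superiority(df, parameter="zr") == "4/4/4"


class TestRetestReliability:
    def _subjects(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return [DiffusionParams(a, v, t0, zr)
                for a, v, t0, zr in zip(rng.uniform(0.6, 1.8, n),
                                        rng.uniform(-3, 3, n),
                                        rng.uniform(0.2, 0.5, n),
                                        rng.uniform(0.35, 0.65, n))]

    def test_identical_sessions_give_unit_reliability(self):
        s = self._subjects()
        rel = retest_reliability(s, s)
        assert all(rel[k] == pytest.approx(1.0, abs=1e-9)
                   for k in ("a", "v", "t0", "zr"))
        assert rel["mean_retest_reliability"] == pytest.approx(1.0, abs=1e-6)

    def test_independent_sessions_near_zero(self):
        rel = retest_reliability(self._subjects(seed=1), self._subjects(seed=2))
        assert abs(rel["mean_retest_reliability"]) < 0.45  # null case, n=20

    def test_zero_variance_flagged_as_nan(self):
        s1 = self._subjects()
        s2 = [p.replace(t0=0.3) for p in self._subjects(seed=3)]
        rel = retest_reliability(s1, s2)
        assert np.isnan(rel["t0"])
        assert np.isfinite(rel["mean_retest_reliability"])

    def test_requires_paired_sessions(self):
        with pytest.raises(ValueError):
            retest_reliability(self._subjects(5), self._subjects(4))

    def test_two_drift_uses_v_total(self):
        rng = np.random.default_rng(4)
        s1 = [DiffusionParams(1.2, -2 + e, 0.3, 0.5, v1=2 + 2 * e)
              for e in rng.normal(0, 0.5, 15)]  # v_total = 4 + e varies
        s2 = [p.replace(v=p.v + 0.01, v1=p.v1 - 0.01) for p in s1]
        rel = retest_reliability(s1, s2)
        assert rel["v"] == pytest.approx(1.0, abs=1e-6)
        assert np.isnan(rel["zr"])  # constant across subjects
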