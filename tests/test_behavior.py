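"""Signal-detection metrics: d', learning curves, psychometric fits, detection time."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from audlearn.behavior import (
    detection_time,
    dprime,
    fit_psychometric,
    learning_curve,
    stage_dprime,
)
from audlearn.synthetic import StageSpec, generate_behavior_log
from audlearn.synthetic.behavior import BehaviorLog


class TestDPrime:
    @pytest.mark.parametrize(
        "hits,misses,fas,crs,expected",
        [
            (50, 50, 50, 50, 0.0),  # equal rates
            (84134, 15866, 15866, 84134, 2.0),  # z(0.84134)=1, z(0.15866)=-1
            (69146, 30854, 30854, 69146, 1.0),  # inverse normal of +-0.5
        ],
    )
    def test_inverse_normal_identities(self, hits, misses, fas, crs, expected):
        assert dprime(hits, misses, fas, crs).dprime == pytest.approx(
            expected, abs=1e-3
        )

    def test_clipping_closed_form(self):
        # perfect 100/100 performance: d' = 2 z(1 - 1/200) ~= 5.15
        res = dprime(100, 0, 0, 100)
        assert res.clipped
        assert res.dprime == pytest.approx(2 * norm.ppf(1 - 1 / 200))
        assert res.dprime == pytest.approx(5.152, abs=5e-3)

    @given(
        h=st.integers(1, 99), f=st.integers(1, 99)
    )
    def test_antisymmetry(self, h, f):
        d1 = dprime(h, 100 - h, f, 100 - f).dprime
        d2 = dprime(f, 100 - f, h, 100 - h).dprime
        assert d1 == pytest.approx(-d2)

    @given(h=st.integers(2, 98), f=st.integers(2, 98))
    def test_monotonicity_in_rates(self, h, f):
        base = dprime(h, 100 - h, f, 100 - f).dprime
        assert dprime(h + 1, 99 - h, f, 100 - f).dprime > base
        assert dprime(h, 100 - h, f + 1, 99 - f).dprime < base

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            dprime(0, 0, 5, 5)


class TestLearningCurve:
    def test_constant_rates_recovered_per_bin(self):
        stages = [StageSpec(nontarget_khz=7.1, n_trials=4000, p_hit=0.9, p_fa=0.1)]
        log = generate_behavior_log(stages, seed=8)
        curve = learning_curve(log, bin_trials=200)
        expected = norm.ppf(0.9) - norm.ppf(0.1)  # 2.563
        assert abs(curve.dprime.mean() - expected) < 0.15
        assert (curve.dprime - expected).abs().max() < 1.2  # per-bin noise bound

    def test_single_bin_when_bin_exceeds_log(self):
        log = generate_behavior_log(
            [StageSpec(nontarget_khz=7.1, n_trials=40, p_hit=0.9, p_fa=0.1)], seed=1
        )
        assert len(learning_curve(log, bin_trials=10_000)) == 1

    def test_empty_log_rejected(self):
        log = generate_behavior_log(
            [StageSpec(nontarget_khz=7.1, n_trials=10, p_hit=0.5, p_fa=0.5)], seed=0
        )
        empty = BehaviorLog(trials=log.trials.iloc[0:0])
        with pytest.raises(ValueError):
            learning_curve(empty)

    def test_stage_final_window_ignores_early_trials(self):
        # first two thirds at chance, last third perfect: stage d' reflects the end
        rows = []
        for i in range(300):
            is_target = i % 2 == 0
            if i < 200:
                licked = (i // 2) % 2 == 0  # chance-like alternation
            else:
                licked = is_target  # perfect
            kind = "target" if is_target else "nontarget"
            rows.append(
                dict(
                    mouse_id="m0", timestamp_s=float(i), stage_id="stage_0",
                    stimulus_kind=kind, stimulus_khz=10.0 if is_target else 7.1,
                    licked=licked,
                    outcome=BehaviorLog.OUTCOME[(kind, licked)],
                    lick_times_ms="",
                )
            )
        log = BehaviorLog(trials=pd.DataFrame(rows))
        table = stage_dprime(log, final_fraction=1 / 3)
        res = table.iloc[0]
        assert res.hit_rate > 0.9 and res.fa_rate < 0.1
        assert res.dprime > 4  # clipped perfect performance, not diluted by the start


class TestPsychometric:
    @staticmethod
    def _simulate(seed, boundary_khz=8.4, slope=6.0, trials=200):
        rng = np.random.default_rng(seed)
        freqs = np.geomspace(7.0, 10.0, 8)
        f_all, licked = [], []
        for f in freqs:
            p = 0.05 + 0.9 / (1 + np.exp(-slope * np.log2(f / boundary_khz)))
            f_all.extend([f] * trials)
            licked.extend(rng.random(trials) < p)
        return np.array(f_all), np.array(licked)

    def test_boundary_recovery_median_error(self):
        errors = []
        for seed in range(50):
            f, licked = self._simulate(seed)
            fit = fit_psychometric(f, licked)
            errors.append(abs(np.log2(fit.decision_boundary_khz / 8.4)))
        assert np.median(errors) < 0.05  # octaves

    def test_flat_curve_flagged_degenerate(self):
        f = np.repeat(np.geomspace(7, 10, 6), 50)
        licked = np.tile([True, False], f.size // 2)
        fit = fit_psychometric(f, licked)
        assert fit.degenerate

    def test_step_boundary_bracketed(self):
        freqs = np.array([7.0, 8.0, 9.0, 10.0])
        f = np.repeat(freqs, 100)
        licked = np.concatenate(
            [np.zeros(200, dtype=bool), np.ones(200, dtype=bool)]
        )
        fit = fit_psychometric(f, licked)
        assert 8.0 <= fit.decision_boundary_khz <= 9.0

    def test_too_few_frequencies_rejected(self):
        with pytest.raises(ValueError):
            fit_psychometric(np.array([7.0, 8.0, 7.0]), np.array([0, 1, 0]))


class TestDetectionTime:
    @staticmethod
    def _rasters(rate_before, rate_after, change_ms, n, duration_ms, seed):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            pre = rng.uniform(0, change_ms, rng.poisson(rate_before * change_ms / 1000))
            post = rng.uniform(
                change_ms, duration_ms,
                rng.poisson(rate_after * (duration_ms - change_ms) / 1000),
            )
            out.append(np.concatenate([pre, post]))
        return out

    def test_identical_processes_not_detected(self):
        hits = self._rasters(1.0, 1.0, 500, 50, 2000, seed=1)
        crs = self._rasters(1.0, 1.0, 500, 50, 2000, seed=2)
        res = detection_time(hits, crs, duration_ms=2000)
        assert not res.detected and res.time_ms is None

    def test_change_point_recovered_within_one_bin(self):
        hits = self._rasters(0.2, 5.0, 500, 100, 2000, seed=3)
        crs = self._rasters(0.2, 0.2, 500, 100, 2000, seed=4)
        res = detection_time(hits, crs, duration_ms=2000, bin_ms=50)
        assert res.detected
        assert abs(res.time_ms - 500) <= 75  # within one bin of the change

    def test_alpha_one_returns_first_bin(self):
        hits = self._rasters(2.0, 2.0, 500, 20, 1000, seed=5)
        crs = self._rasters(1.0, 1.0, 500, 20, 1000, seed=6)
        res = detection_time(hits, crs, duration_ms=1000, bin_ms=50, alpha=1.0)
        assert res.detected and res.time_ms == pytest.approx(25.0)

    def test_trial_count_precondition(self):
        with pytest.raises(ValueError):
            detection_time([np.array([1.0])] * 5, [np.array([1.0])] * 5, 1000)

    def test_lick_beyond_duration_rejected(self):
        good = [np.array([10.0])] * 10
        bad = [np.array([5000.0])] * 10
        with pytest.raises(ValueError):
            detection_time(good, bad, duration_ms=2000)
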