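"""Alarm generation, SOP/SPH scoring, significance, aggregation."""

import math

import numpy as np
import pytest

from csspm.evaluation import (
    AlarmConfig,
    ScoringConfig,
    aggregate,
    generate_alarms,
    random_predictor_p,
    score_alarms,
)


def stream(states, segment_s=30.0, t0=30.0):
    states = np.asarray(states, dtype=int)
    times = t0 + segment_s * np.arange(len(states))
    return times, states


def brute_force_alarms(times, states, cfg: AlarmConfig):
    """Independent sliding-window scan (reference oracle)."""
    alarms, last = [], -math.inf
    for i in range(len(states)):
        if i + 1 < cfg.n:
            continue
        if sum(states[i + 1 - cfg.n : i + 1]) >= cfg.k:
            if times[i] - last >= cfg.refractory_s:
                alarms.append(times[i])
                last = times[i]
    return alarms


class TestGenerateAlarms:
    cfg = AlarmConfig()  # k=8, n=10, refractory 1800 s

    def test_eight_of_ten_triggers(self):
        t, s = stream([1, 1, 1, 1, 0, 1, 1, 0, 1, 1])
        assert len(generate_alarms(t, s, self.cfg)) == 1

    def test_seven_of_ten_does_not(self):
        t, s = stream([1, 1, 1, 1, 0, 1, 0, 0, 1, 1])
        assert generate_alarms(t, s, self.cfg) == []

    def test_refractory_spacing_under_continuous_preictal(self):
        """2 h of continuous preictal -> alarms exactly 30 min apart."""
        t, s = stream([1] * 240)
        alarms = generate_alarms(t, s, self.cfg)
        assert len(alarms) == 4
        np.testing.assert_allclose(np.diff(alarms), 1800.0)

    def test_short_stream_cannot_trigger(self):
        t, s = stream([1] * 9)
        assert generate_alarms(t, s, self.cfg) == []

    def test_unordered_stream_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            generate_alarms([60.0, 30.0], [1, 1], self.cfg)

    def test_causality_under_truncation(self):
        rng = np.random.default_rng(0)
        cfg = AlarmConfig(k=2, n=3, refractory_s=90.0)
        for _ in range(50):
            t, s = stream(rng.integers(0, 2, size=40))
            full = generate_alarms(t, s, cfg)
            for cut in (10, 25, 40):
                part = generate_alarms(t[:cut], s[:cut], cfg)
                assert part == [a for a in full if a <= t[cut - 1]]


class TestScoreAlarms:
    cfg = ScoringConfig()  # SOP 1800 s, SPH 300 s

    def test_alarm_five_minutes_before_onset_is_tp(self):
        res = score_alarms([1000.0], [1300.0], self.cfg, interictal_hours=1.0)
        assert (res.tp, res.fn, res.fp) == (1, 0, 0)
        assert res.sensitivity == 100.0

    def test_alarm_two_minutes_before_onset_misses(self):
        res = score_alarms([1000.0], [1120.0], self.cfg, interictal_hours=1.0)
        assert (res.tp, res.fn, res.fp) == (0, 1, 1)

    def test_sop_end_boundary_is_closed(self):
        res = score_alarms([0.0], [2100.0], self.cfg, 1.0)
        assert res.tp == 1
        res = score_alarms([0.0], [2100.1], self.cfg, 1.0)
        assert res.tp == 0

    def test_no_alarms_all_missed(self):
        res = score_alarms([], [1.0, 2.0, 3.0], self.cfg, 2.0)
        assert (res.tp, res.fn, res.fp) == (0, 3, 0)
        assert res.sensitivity == 0.0
        assert res.fpr_per_hour == 0.0

    def test_each_alarm_claims_one_seizure(self):
        # one alarm could cover both onsets; only the earliest is credited
        res = score_alarms([0.0], [400.0, 500.0], self.cfg, 1.0)
        assert (res.tp, res.fn) == (1, 1)

    def test_tp_plus_fn_equals_seizure_count(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            alarms = sorted(rng.uniform(0, 20000, size=rng.integers(0, 6)))
            onsets = sorted(rng.uniform(0, 20000, size=rng.integers(1, 6)))
            res = score_alarms(alarms, onsets, self.cfg, 5.0)
            assert res.tp + res.fn == len(onsets)
            assert res.tp + res.fp == len(alarms)

    def test_zero_interictal_with_fp_rejected(self):
        with pytest.raises(ValueError, match="interictal"):
            score_alarms([5.0], [100000.0], self.cfg, 0.0)


class TestRandomPredictor:
    def test_zero_fpr_zero_p(self):
        assert random_predictor_p(0.0, 1800.0, 1, 5) == 0.0

    def test_zero_predicted_gives_one(self):
        assert random_predictor_p(0.7, 1800.0, 0, 5) == 1.0

    def test_matches_binomial_sum(self):
        fpr, sop = 0.5, 1800.0
        prob = 1 - math.exp(-fpr * sop / 3600.0)
        K, k = 5, 3
        ref = sum(math.comb(K, i) * prob ** i * (1 - prob) ** (K - i)
                  for i in range(k, K + 1))
        assert random_predictor_p(fpr, sop, k, K) == pytest.approx(ref, abs=1e-12)

    def test_monotone_in_k_and_fpr(self):
        ps = [random_predictor_p(0.4, 1800.0, k, 8) for k in range(1, 9)]
        assert all(a >= b for a, b in zip(ps[:-1], ps[1:]))
        pf = [random_predictor_p(f, 1800.0, 3, 8) for f in (0.1, 0.3, 0.6, 1.2)]
        assert all(a <= b for a, b in zip(pf[:-1], pf[1:]))

    def test_overprediction_rejected(self):
        with pytest.raises(ValueError):
            random_predictor_p(0.1, 1800.0, 6, 5)


class TestAggregate:
    def _res(self, sens, fpr=0.5, p=0.01):
        from csspm.evaluation import EvalResult
        return EvalResult(tp=1, fn=0, fp=1, interictal_hours=2.0,
                          sensitivity=sens, fpr_per_hour=fpr, p_value=p,
                          n_seizures=1)

    def test_identical_runs_zero_std(self):
        out = aggregate([[self._res(80.0), self._res(80.0)]])
        assert out["sensitivity_mean"] == 80.0
        assert out["sensitivity_std"] == 0.0

    def test_fold_mean(self):
        out = aggregate([[self._res(100.0)] * 2, [self._res(50.0)] * 2])
        assert out["sensitivity_mean"] == 75.0

    def test_single_run_warns(self):
        with pytest.warns(UserWarning, match="single run"):
            out = aggregate([[self._res(60.0)]])
        assert out["sensitivity_std"] == 0.0
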