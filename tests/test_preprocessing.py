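"""Labeling, segmentation, STFT band exclusion and class balancing."""

import numpy as np
import pytest

from csspm.preprocessing import (
    INTERICTAL,
    PREICTAL,
    LabelingRules,
    StftConfig,
    compute_balance_stride,
    label_periods,
    segment_and_stft,
    select_subjects,
    window_count,
)
from csspm.synthetic import EegRecord

H = 3600.0


def _record(duration_h: float, seizures, fs: float = 64.0,
            n_samples: int | None = None) -> EegRecord:
    n = n_samples or int(duration_h * H * fs)
    return EegRecord(
        signal=np.zeros((2, n)),
        sampling_rate=fs,
        seizure_intervals=seizures,
        subject_id="t",
    )


def _states(periods, state):
    return [iv for iv, s in periods if s == state]


class TestLabelPeriods:
    def test_single_seizure_midrecord(self):
        """One 60-s seizure at t = 10 h in a 20 h record."""
        rec = _record(20, [(10 * H, 10 * H + 60)])
        periods = label_periods(rec, LabelingRules())
        assert _states(periods, PREICTAL) == [(9.5 * H, 10 * H)]
        inter = _states(periods, INTERICTAL)
        assert inter[0] == (0.0, 6 * H)
        assert inter[1] == pytest.approx((14 * H + 60, 20 * H))

    def test_close_seizure_not_evaluated(self):
        """A seizure starting 20 min after the previous one's end yields no
        preictal interval."""
        rec = _record(20, [(10 * H, 10 * H + 60), (10 * H + 60 + 1200,
                                                  10 * H + 60 + 1260)])
        periods = label_periods(rec, LabelingRules())
        pre = _states(periods, PREICTAL)
        assert pre == [(9.5 * H, 10 * H)]

    def test_no_seizures_all_interictal(self):
        rec = _record(5, [])
        periods = label_periods(rec, LabelingRules())
        assert periods == [((0.0, 5 * H), INTERICTAL)]

    def test_partition_is_exact(self):
        rec = _record(20, [(8 * H, 8 * H + 120), (15 * H, 15 * H + 60)])
        periods = label_periods(rec, LabelingRules())
        assert periods[0][0][0] == 0.0
        assert periods[-1][0][1] == pytest.approx(20 * H)
        for (a, b), _ in periods:
            assert b > a
        for ((_, b1), _), ((a2, _), _) in zip(periods[:-1], periods[1:]):
            assert a2 == pytest.approx(b1)


class TestSelectSubjects:
    rules = LabelingRules()

    def _subject(self, n_seizures, duration_h=48):
        seizures = [(6 * H + i * 2 * H, 6 * H + i * 2 * H + 60)
                    for i in range(n_seizures)]
        return _record(duration_h, seizures, fs=1.0)

    def test_too_few_seizures_excluded(self):
        assert select_subjects([self._subject(3)], self.rules) == []

    def test_too_frequent_excluded(self):
        """Twelve seizures within a single day exceed the rate limit."""
        rec = _record(24, [(H + 600 * i, H + 600 * i + 30) for i in range(12)],
                      fs=1.0)
        assert select_subjects([rec], self.rules) == []

    def test_moderate_subject_retained(self):
        rec = self._subject(5, duration_h=120)
        assert select_subjects([rec], self.rules) == [rec]


class TestSegmentAndStft:
    def test_preictal_window_count(self, small_stft):
        """An 1800-s interval at non-overlapping 30-s stride gives 60 samples."""
        rec = _record(1, [], fs=64.0)
        periods = [((0.0, 1800.0), PREICTAL)]
        s = segment_and_stft(rec, periods, small_stft, stride_s=30.0)
        assert len(s) == 60
        assert (s.y == 1).all()

    def test_zero_signal_zero_spectrogram(self, small_stft):
        rec = _record(1, [], fs=64.0)
        s = segment_and_stft(rec, [((0.0, 300.0), INTERICTAL)], small_stft, 30.0)
        assert np.all(s.x == 0)

    def test_powerline_band_removed(self):
        """A pure 60 Hz input retains < 1% of its unfiltered energy."""
        fs = 256.0
        n = int(300 * fs)
        t = np.arange(n) / fs
        sig = np.sin(2 * np.pi * 60.0 * t)
        rec = EegRecord(np.stack([sig, sig]), fs, [], "line")
        cfg = StftConfig()
        filtered = segment_and_stft(rec, [((0.0, 300.0), INTERICTAL)], cfg, 30.0)
        unfiltered = segment_and_stft(
            rec, [((0.0, 300.0), INTERICTAL)],
            StftConfig(excluded_bands=[], drop_dc=False), 30.0)
        e_f = float((filtered.x ** 2).sum())
        e_u = float((unfiltered.x ** 2).sum())
        assert e_f < 0.01 * e_u

    def test_excluded_bins_absent_not_zeroed(self):
        fs = 256.0
        cfg = StftConfig()
        freqs = cfg.kept_frequencies(fs)
        assert not np.any((freqs >= 57) & (freqs <= 63))
        assert not np.any((freqs >= 117) & (freqs <= 123))
        assert not np.any(freqs == 0)
        full = np.fft.rfftfreq(cfg.stft_window, 1 / fs)
        n_excl = int(np.sum(((full >= 57) & (full <= 63))
                            | ((full >= 117) & (full <= 123)) | (full == 0)))
        assert len(freqs) == len(full) - n_excl

    def test_no_straddling_and_uniform_bins(self, small_record, small_rules,
                                            small_stft):
        periods = label_periods(small_record, small_rules)
        s = segment_and_stft(small_record, periods, small_stft, 30.0)
        spans = {(a, b): st for (a, b), st in periods}
        for i in range(len(s)):
            t0 = s.segment_start[i]
            t1 = t0 + small_stft.segment_length
            holder = [st for (a, b), st in spans.items()
                      if a - 1e-6 <= t0 and t1 <= b + 1e-6]
            assert len(holder) == 1
            assert holder[0] == (PREICTAL if s.y[i] == 1 else INTERICTAL)
        assert s.x.shape[2] == len(s.freqs)

    def test_short_interval_yields_nothing(self, small_stft):
        rec = _record(1, [], fs=64.0)
        s = segment_and_stft(rec, [((0.0, 10.0), INTERICTAL)], small_stft, 30.0)
        assert len(s) == 0


class TestBalanceStride:
    cfg = StftConfig()

    def test_no_oversampling_when_already_balanced(self):
        spec = compute_balance_stride(3600.0, 100, self.cfg)
        assert spec.stride_s == 30.0
        assert spec.target_count == 120

    def test_exact_inversion(self):
        """1800 s of preictal, target 120 -> stride (1800-30)/119, 120 windows."""
        spec = compute_balance_stride(1800.0, 120, self.cfg)
        assert spec.stride_s == pytest.approx(1770.0 / 119.0)
        assert spec.target_count == 120
        assert window_count(1800.0, 30.0, spec.stride_s) == 120

    def test_target_sixty_gives_nonoverlapping(self):
        spec = compute_balance_stride(1800.0, 60, self.cfg)
        assert spec.stride_s == 30.0

    def test_too_short_preictal_errors(self):
        with pytest.raises(ValueError, match="shorter than one segment"):
            compute_balance_stride(20.0, 100, self.cfg)

    @pytest.mark.parametrize("target", [61, 75, 90, 113, 200, 500])
    def test_never_overshoots_by_more_than_one(self, target):
        spec = compute_balance_stride(1800.0, target, self.cfg)
        got = window_count(1800.0, 30.0, spec.stride_s)
        assert got <= target + 1
        assert 0 < spec.stride_s <= 30.0

    def test_multiple_intervals(self):
        spec = compute_balance_stride(5 * 1800.0, 300, self.cfg, n_intervals=5)
        assert spec.stride_s == 30.0  # 5 x 60 windows already reach 300
        spec = compute_balance_stride(5 * 1800.0, 500, self.cfg, n_intervals=5)
        got = 5 * window_count(1800.0, 30.0, spec.stride_s)
        assert abs(got - 500) <= 1
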