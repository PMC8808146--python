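"""From annotated recordings to labeled/unlabeled 30-s STFT samples.

The labeling follows the standard seizure-prediction convention: the preictal
class is the 30 minutes before an onset, the interictal class is everything
more than 4 hours away from any seizure boundary, and the rest (ictal,
postictal, guard margins) is excluded from the task.  A seizure that starts
less than 30 minutes after the previous one ends is not evaluable and
contributes no preictal interval.

Segments are 30-s windows converted to per-channel magnitude STFT images with
the DC bin and the power-line bands (57-63 Hz, 117-123 Hz by default) removed.
Class imbalance in the training set is addressed by re-sampling the preictal
intervals with an overlapping stride chosen per subject so that the preictal
sample count approaches the interictal count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

from .synthetic import EegRecord

__all__ = [
    "LabelingRules",
    "StftConfig",
    "BalanceSpec",
    "SegmentSample",
    "SampleSet",
    "label_periods",
    "evaluable_seizures",
    "select_subjects",
    "segment_and_stft",
    "compute_balance_stride",
]

logger = logging.getLogger(__name__)

PREICTAL, INTERICTAL, EXCLUDED = "preictal", "interictal", "excluded"


@dataclass
class LabelingRules:
    """State-labeling and subject-selection rules.

    preictal_window : 1800 s before each evaluable onset -> preictal class.
    interictal_margin : 14400 s (4 h) guard around every seizure; only time
        farther than this from all seizure boundaries is interictal.
    min_seizure_interval : 1800 s; a seizure starting sooner than this after
        the previous seizure's end is not evaluated (no preictal interval).
    max_seizures_per_day : subjects seizing at >= this daily rate are dropped.
    min_leading_seizures : minimum evaluable seizures for subject selection.
    """

    preictal_window: float = 1800.0
    interictal_margin: float = 14400.0
    min_seizure_interval: float = 1800.0
    max_seizures_per_day: int = 10
    min_leading_seizures: int = 4

    def validate(self) -> None:
        if min(self.preictal_window, self.interictal_margin,
               self.min_seizure_interval) <= 0:
            raise ValueError("all durations must be positive")
        if self.max_seizures_per_day <= 0 or self.min_leading_seizures <= 0:
            raise ValueError("counts must be positive")


@dataclass
class StftConfig:
    """Segmentation and short-time Fourier transform parameters.

    The transform uses a Hann window of ``stft_window`` samples with
    fractional overlap ``stft_overlap``, magnitude output, no log scaling.
    Frequency bins whose center lies at 0 Hz (if ``drop_dc``) or inside any of
    ``excluded_bands`` (inclusive bounds, Hz) are removed, not zeroed.
    """

    segment_length: float = 30.0
    stft_window: int = 256
    stft_overlap: float = 0.5
    excluded_bands: list[tuple[float, float]] = field(
        default_factory=lambda: [(57.0, 63.0), (117.0, 123.0)]
    )
    drop_dc: bool = True

    @property
    def hop(self) -> int:
        h = int(round(self.stft_window * (1.0 - self.stft_overlap)))
        return max(h, 1)

    def validate(self, sampling_rate: float) -> None:
        if self.segment_length <= 0 or self.stft_window < 2:
            raise ValueError("segment_length and stft_window must be positive")
        if not (0.0 <= self.stft_overlap < 1.0):
            raise ValueError("stft_overlap must lie in [0, 1)")
        nyq = sampling_rate / 2.0
        for lo, hi in self.excluded_bands:
            if lo > nyq:
                continue  # band entirely above Nyquist: vacuous, allowed
            if not (0 <= lo < hi):
                raise ValueError(f"malformed excluded band ({lo}, {hi})")
        if int(round(self.segment_length * sampling_rate)) < self.stft_window:
            raise ValueError("segment shorter than one STFT window")

    def kept_frequencies(self, sampling_rate: float) -> np.ndarray:
        """Centers (Hz) of the frequency bins retained after exclusion."""
        f = np.fft.rfftfreq(self.stft_window, d=1.0 / sampling_rate)
        keep = np.ones_like(f, dtype=bool)
        if self.drop_dc:
            keep &= f > 0
        for lo, hi in self.excluded_bands:
            keep &= ~((f >= lo) & (f <= hi))
        return f[keep]


@dataclass
class BalanceSpec:
    """Overlapping-stride choice for preictal oversampling."""

    stride_s: float
    target_count: int


@dataclass
class SegmentSample:
    """One 30-s STFT sample: image x, optional label y, provenance."""

    x: np.ndarray  # [channels, freq_bins, time_bins]
    y: int | None  # 0 interictal, 1 preictal, None if unlabeled
    is_labeled: bool
    source_recording: str
    segment_start: float


@dataclass
class SampleSet:
    """A column-oriented collection of :class:`SegmentSample`.

    ``y`` uses -1 for absent labels; ``labeled`` marks membership in the
    labeled index set.  ``freqs`` records the retained bin centers so that
    band-exclusion is auditable downstream.
    """

    x: np.ndarray          # (n, channels, freq, time)
    y: np.ndarray          # (n,) int8, -1 = unlabeled
    labeled: np.ndarray    # (n,) bool
    segment_start: np.ndarray  # (n,) float seconds
    source: np.ndarray     # (n,) str
    freqs: np.ndarray      # (freq,) Hz

    def __len__(self) -> int:
        return self.x.shape[0]

    def __getitem__(self, i: int) -> SegmentSample:
        lab = bool(self.labeled[i])
        return SegmentSample(
            x=self.x[i],
            y=int(self.y[i]) if lab else None,
            is_labeled=lab,
            source_recording=str(self.source[i]),
            segment_start=float(self.segment_start[i]),
        )

    def subset(self, idx) -> "SampleSet":
        idx = np.asarray(idx)
        return SampleSet(self.x[idx], self.y[idx], self.labeled[idx],
                         self.segment_start[idx], self.source[idx], self.freqs)

    def as_unlabeled(self) -> "SampleSet":
        """Copy with labels stripped (assignment to the unlabeled role)."""
        return replace(
            self,
            y=np.full(len(self), -1, dtype=np.int8),
            labeled=np.zeros(len(self), dtype=bool),
        )

    @staticmethod
    def concatenate(parts: list["SampleSet"]) -> "SampleSet":
        parts = [p for p in parts if len(p) > 0]
        if not parts:
            raise ValueError("nothing to concatenate")
        f0 = parts[0].freqs
        for p in parts[1:]:
            if p.x.shape[1:] != parts[0].x.shape[1:] or not np.allclose(p.freqs, f0):
                raise ValueError("sample sets have incompatible shapes or bins")
        return SampleSet(
            x=np.concatenate([p.x for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            labeled=np.concatenate([p.labeled for p in parts]),
            segment_start=np.concatenate([p.segment_start for p in parts]),
            source=np.concatenate([p.source for p in parts]),
            freqs=f0,
        )


def evaluable_seizures(
    record: EegRecord, rules: LabelingRules
) -> list[tuple[float, float]]:
    """Seizures retained after the minimum-interval exclusion.

    A seizure whose onset falls less than ``min_seizure_interval`` after the
    previous seizure's end (previous in the full annotation, evaluable or not)
    is dropped and contributes no preictal interval.
    """
    out = []
    prev_end = -math.inf
    for onset, offset in sorted(record.seizure_intervals):
        if onset - prev_end >= rules.min_seizure_interval:
            out.append((onset, offset))
        prev_end = offset
    return out


def label_periods(
    record: EegRecord, rules: LabelingRules
) -> list[tuple[tuple[float, float], str]]:
    """Partition [0, duration) into preictal / interictal / excluded intervals.

    preictal   = [onset - preictal_window, onset) of each evaluable seizure;
    interictal = time farther than ``interictal_margin`` from every seizure
                 boundary (dropped seizures still cast their margin);
    excluded   = everything else (ictal, margins, preictal of dropped
                 seizures).

    Returns half-open ``((start, end), state)`` intervals sorted by start,
    covering the record exactly.
    """
    rules.validate()
    dur = record.duration
    seizures = sorted(record.seizure_intervals)
    evaluable = evaluable_seizures(record, rules)

    # state priority: excluded margins are overridden only by preictal
    marks = np.empty(0)
    bounds = {0.0, dur}
    for onset, offset in seizures:
        bounds.add(min(max(onset - rules.interictal_margin, 0.0), dur))
        bounds.add(min(max(offset + rules.interictal_margin, 0.0), dur))
    for onset, _ in evaluable:
        bounds.add(min(max(onset - rules.preictal_window, 0.0), dur))
        bounds.add(min(max(onset, 0.0), dur))
    edges = sorted(bounds)

    def state_at(t: float) -> str:
        for onset, _ in evaluable:
            if onset - rules.preictal_window <= t < onset:
                return PREICTAL
        for onset, offset in seizures:
            if onset - rules.interictal_margin <= t < offset + rules.interictal_margin:
                return EXCLUDED
        return INTERICTAL

    out: list[tuple[tuple[float, float], str]] = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a <= 0:
            continue
        s = state_at((a + b) / 2.0)
        if out and out[-1][1] == s:
            out[-1] = ((out[-1][0][0], b), s)
        else:
            out.append(((a, b), s))
    return out


def select_subjects(
    records: list[EegRecord], rules: LabelingRules
) -> list[EegRecord]:
    """Keep subjects with enough evaluable seizures and a moderate seizure rate.

    Retains records with at least ``min_leading_seizures`` evaluable seizures
    and fewer than ``max_seizures_per_day`` seizures per day of recording.
    """
    rules.validate()
    kept = []
    for rec in records:
        n_eval = len(evaluable_seizures(rec, rules))
        days = rec.duration / 86400.0
        rate = len(rec.seizure_intervals) / days if days > 0 else math.inf
        if n_eval >= rules.min_leading_seizures and rate < rules.max_seizures_per_day:
            kept.append(rec)
        else:
            logger.info(
                "subject %s excluded (%d evaluable seizures, %.2f/day)",
                rec.subject_id, n_eval, rate,
            )
    return kept


def window_count(interval_length: float, segment_length: float, stride: float) -> int:
    """floor((length - segment) / stride) + 1, with a float-safety epsilon."""
    if interval_length < segment_length:
        return 0
    return int(math.floor((interval_length - segment_length) / stride + 1e-9)) + 1


def _stft_magnitude(seg: np.ndarray, cfg: StftConfig, fs: float) -> np.ndarray:
    """Magnitude STFT of one [channels, samples] segment, full frames only.

    Hann window of ``stft_window`` samples at hop ``cfg.hop``; only frames
    entirely inside the segment are produced so every sample of a subject has
    the same time-bin count.
    """
    win = hann(cfg.stft_window, sym=False)
    frames = sliding_window_view(seg, cfg.stft_window, axis=1)[:, :: cfg.hop, :]
    spec = np.fft.rfft(frames * win, axis=2)  # (ch, frames, freq)
    f = np.fft.rfftfreq(cfg.stft_window, d=1.0 / fs)
    keep = np.ones_like(f, dtype=bool)
    if cfg.drop_dc:
        keep &= f > 0
    for lo, hi in cfg.excluded_bands:
        keep &= ~((f >= lo) & (f <= hi))
    return np.abs(spec[:, :, keep]).transpose(0, 2, 1)  # (ch, freq, time)


def segment_and_stft(
    record: EegRecord,
    intervals: list[tuple[tuple[float, float], str]],
    cfg: StftConfig,
    stride_s: float,
    states: tuple[str, ...] = (PREICTAL, INTERICTAL),
    source: str | None = None,
) -> SampleSet:
    """Slice labeled intervals into 30-s windows and transform each to a
    magnitude STFT image.

    Windows lie fully inside a single interval; ``stride_s`` may differ per
    state via repeated calls.  Intervals shorter than one segment yield no
    samples (logged).  Returns an empty SampleSet if nothing fits.
    """
    cfg.validate(record.sampling_rate)
    if stride_s <= 0:
        raise ValueError("stride must be positive")
    fs = record.sampling_rate
    seg_samp = int(round(cfg.segment_length * fs))
    src = source if source is not None else record.subject_id

    xs, ys, starts = [], [], []
    for (a, b), state in intervals:
        if state not in states:
            continue
        k = window_count(b - a, cfg.segment_length, stride_s)
        if k == 0:
            logger.info("interval (%.1f, %.1f) shorter than one segment; skipped", a, b)
            continue
        label = 1 if state == PREICTAL else 0
        for j in range(k):
            t0 = a + j * stride_s
            i0 = int(round(t0 * fs))
            seg = record.signal[:, i0 : i0 + seg_samp]
            if seg.shape[1] < seg_samp:
                continue
            xs.append(_stft_magnitude(seg, cfg, fs))
            ys.append(label)
            starts.append(t0)

    freqs = cfg.kept_frequencies(fs)
    if not xs:
        nt = 0
        x = np.empty((0, record.n_channels, len(freqs), nt), dtype=np.float32)
        return SampleSet(
            x=x,
            y=np.empty(0, dtype=np.int8),
            labeled=np.empty(0, dtype=bool),
            segment_start=np.empty(0),
            source=np.empty(0, dtype=object),
            freqs=freqs,
        )
    x = np.stack(xs).astype(np.float32)
    return SampleSet(
        x=x,
        y=np.asarray(ys, dtype=np.int8),
        labeled=np.ones(len(ys), dtype=bool),
        segment_start=np.asarray(starts, dtype=float),
        source=np.asarray([src] * len(ys), dtype=object),
        freqs=freqs,
    )


def compute_balance_stride(
    total_preictal_s: float,
    n_interictal_samples: int,
    cfg: StftConfig,
    n_intervals: int = 1,
) -> BalanceSpec:
    """Choose the overlapping stride S that balances the preictal class.

    Assuming ``n_intervals`` equal-length preictal intervals totalling
    ``total_preictal_s`` seconds, returns the stride in (0, segment_length]
    whose window count comes closest to ``n_interictal_samples`` without
    exceeding it by more than one window.  If the non-overlapping stride
    already reaches the target, no oversampling is done.
    """
    if total_preictal_s <= 0 or n_interictal_samples <= 0 or n_intervals <= 0:
        raise ValueError("inputs must be positive")
    seg = cfg.segment_length
    per = total_preictal_s / n_intervals
    if per < seg:
        raise ValueError(
            f"preictal intervals ({per:g} s) shorter than one segment ({seg:g} s)"
        )
    target = int(n_interictal_samples)
    base = n_intervals * window_count(per, seg, seg)
    if base >= target:
        return BalanceSpec(stride_s=seg, target_count=base)

    length = per - seg  # slideable span per interval
    best: tuple[float, float, int] | None = None  # (|diff|, stride, count)
    for c in (target // n_intervals, -(-target // n_intervals)):  # floor, ceil
        if c < 2:
            continue
        stride = length / (c - 1)
        if stride > seg or stride <= 0:
            continue
        count = n_intervals * window_count(per, seg, stride)
        if count > target + 1:
            continue
        cand = (abs(count - target), stride, count)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        return BalanceSpec(stride_s=seg, target_count=base)
    return BalanceSpec(stride_s=float(best[1]), target_count=int(best[2]))
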