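"""Seeded synthetic EEG with a controllable preictal spectral signature.

The generator emulates annotated long-duration scalp EEG: each channel is an
independent stationary colored-noise background with a 1/f^beta spectrum, and
in the 30 minutes preceding each seizure onset an independent band-limited
noise component is added so that power inside ``preictal_band`` is scaled by
``preictal_power_gain`` (independent components add in power, so the band-power
ratio preictal/interictal equals the gain exactly in expectation).  Seizures
themselves carry a high-amplitude oscillation and are never used for training.

This is deliberately not a physiological simulation: no artifacts, no
nonstationary background, hard label boundaries.  Its purpose is to make every
downstream stage of the pipeline testable with a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SyntheticConfig", "EegRecord", "generate_record"]

#: seconds of elevated band power before each seizure onset
PREICTAL_WINDOW_S = 1800.0


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic EEG generator.

    Parameters
    ----------
    n_channels : int
        Number of EEG channels (independent background noise per channel).
    sampling_rate : float
        Sampling rate in Hz.  Scalp EEG databases such as CHB-MIT use 256 Hz;
        desk-scale tests may use less.
    duration : float
        Record length in seconds.
    seizure_onsets, seizure_durations : list of float
        Seizure onset times (seconds) and durations (seconds).  Intervals must
        be sorted and non-overlapping.
    preictal_band : (float, float)
        Frequency band (Hz) whose power is elevated before each onset.
    preictal_power_gain : float
        Multiplicative band-power factor >= 1 in the 30 min before onset.
        A gain of 1 makes preictal and interictal indistinguishable.
    background_spectrum_exponent : float
        Slope beta of the 1/f^beta background power spectrum.
    background_rms : float
        Per-channel RMS amplitude of the background, in microvolt-scale
        arbitrary units.
    ictal_frequency, ictal_amplitude_factor : float
        The within-seizure oscillation: frequency in Hz and amplitude as a
        multiple of ``background_rms``.
    seed : int
        Seed; identical configs produce bit-identical records.
    """

    n_channels: int = 4
    sampling_rate: float = 256.0
    duration: float = 3600.0
    seizure_onsets: list[float] = field(default_factory=list)
    seizure_durations: list[float] = field(default_factory=list)
    preictal_band: tuple[float, float] = (4.0, 8.0)
    preictal_power_gain: float = 2.0
    background_spectrum_exponent: float = 1.0
    background_rms: float = 10.0
    ictal_frequency: float = 3.0
    ictal_amplitude_factor: float = 5.0
    seed: int = 0
    subject_id: str = "synthetic"

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if len(self.seizure_onsets) != len(self.seizure_durations):
            raise ValueError("seizure_onsets and seizure_durations differ in length")
        if self.preictal_power_gain < 1.0:
            raise ValueError("preictal_power_gain must be >= 1")
        lo, hi = self.preictal_band
        if not (0.0 < lo < hi <= self.sampling_rate / 2):
            raise ValueError("preictal_band must satisfy 0 < low < high <= Nyquist")
        prev_end = -np.inf
        for onset, dur in zip(self.seizure_onsets, self.seizure_durations):
            if dur <= 0:
                raise ValueError("seizure durations must be positive")
            if onset < prev_end:
                raise ValueError(
                    f"seizure intervals overlap or are unsorted near t={onset:g} s "
                    f"(previous seizure ends at t={prev_end:g} s)"
                )
            if onset < 0 or onset + dur > self.duration:
                raise ValueError(f"seizure at t={onset:g} s exceeds record bounds")
            prev_end = onset + dur


@dataclass
class EegRecord:
    """An annotated multichannel EEG recording.

    ``signal`` is ``[channels, samples]`` in microvolt-scale arbitrary units;
    ``seizure_intervals`` is a list of ``(onset_s, offset_s)`` pairs.
    """

    signal: np.ndarray
    sampling_rate: float
    seizure_intervals: list[tuple[float, float]]
    subject_id: str = ""

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.sampling_rate

    def validate(self) -> None:
        if self.signal.ndim != 2:
            raise ValueError("signal must be [channels, samples]")
        for onset, offset in self.seizure_intervals:
            if not (0 <= onset < offset <= self.duration + 1e-9):
                raise ValueError(f"seizure interval ({onset}, {offset}) outside record")


def _colored_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance Gaussian noise shaped to a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Brick-wall FFT bandpass (keeps bins with band[0] <= f <= band[1])."""
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.shape[-1], d=1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    return np.fft.irfft(spec, n=x.shape[-1])


def generate_record(config: SyntheticConfig) -> EegRecord:
    """Generate an annotated synthetic EEG record.

    The background of each channel is colored Gaussian noise scaled to
    ``background_rms``.  Within ``[onset - 1800 s, onset)`` of every seizure an
    independent band-limited noise component with variance
    ``(gain - 1) * P_band`` is added, where ``P_band`` is the channel's
    background power inside ``preictal_band`` — a hard-boundary spectral shift
    of exactly ``preictal_power_gain`` in expectation.  During seizures a
    sinusoid of amplitude ``ictal_amplitude_factor * background_rms`` is added.
    Fully reproducible from ``config.seed``.
    """
    config.validate()
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    rng = np.random.default_rng(config.seed)

    signal = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        bg = _colored_noise(rng, n, config.background_spectrum_exponent)
        signal[ch] = bg * config.background_rms

    gain = config.preictal_power_gain
    if gain > 1.0 and config.seizure_onsets:
        for ch in range(config.n_channels):
            # power of the background inside the preictal band, per channel
            p_band = _bandpass(signal[ch], fs, config.preictal_band).var()
            for onset in config.seizure_onsets:
                i0 = max(0, int(round((onset - PREICTAL_WINDOW_S) * fs)))
                i1 = int(round(onset * fs))
                if i1 <= i0:
                    continue
                extra = _bandpass(rng.standard_normal(i1 - i0), fs, config.preictal_band)
                sd = extra.std()
                if sd > 0:
                    extra *= np.sqrt((gain - 1.0) * p_band) / sd
                signal[ch, i0:i1] += extra

    intervals = []
    t = np.arange(n) / fs
    for onset, dur in zip(config.seizure_onsets, config.seizure_durations):
        i0, i1 = int(round(onset * fs)), int(round((onset + dur) * fs))
        osc = config.ictal_amplitude_factor * config.background_rms * np.sin(
            2 * np.pi * config.ictal_frequency * t[i0:i1]
        )
        signal[:, i0:i1] += osc[None, :]
        intervals.append((float(onset), float(onset + dur)))

    rec = EegRecord(
        signal=signal,
        sampling_rate=fs,
        seizure_intervals=intervals,
        subject_id=config.subject_id,
    )
    rec.validate()
    return rec
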