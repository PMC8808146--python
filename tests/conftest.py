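import numpy as np
import pytest

from csspm.preprocessing import LabelingRules, SampleSet, StftConfig
from csspm.synthetic import EegRecord, SyntheticConfig, generate_record


@pytest.fixture(scope="session")
def small_record() -> EegRecord:
    """Two-channel record with four evaluable seizures at a small margin."""
    cfg = SyntheticConfig(
        n_channels=2,
        sampling_rate=64.0,
        duration=11400.0,
        seizure_onsets=[2400.0, 4800.0, 7200.0, 9600.0],
        seizure_durations=[30.0] * 4,
        seed=7,
    )
    return generate_record(cfg)


@pytest.fixture(scope="session")
def small_rules() -> LabelingRules:
    return LabelingRules(interictal_margin=600.0)


@pytest.fixture(scope="session")
def small_stft() -> StftConfig:
    return StftConfig(stft_window=64, stft_overlap=0.0)


def random_sample_set(n: int, n_channels: int = 2, shape=(16, 16),
                      seed: int = 0, label_frac: float = 1.0) -> SampleSet:
    """Synthetic spectrogram-like samples with a weak class-dependent mean."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n).astype(np.int8)
    x = rng.normal(0.0, 1.0, size=(n, n_channels, *shape))
    x[y == 1, :, 4:8, :] += 1.0
    labeled = rng.random(n) < label_frac
    if not labeled.any():
        labeled[0] = True
    y_out = np.where(labeled, y, -1).astype(np.int8)
    return SampleSet(
        x=x.astype(np.float32),
        y=y_out,
        labeled=labeled,
        segment_start=np.arange(n, dtype=float) * 30.0,
        source=np.asarray(["toy"] * n, dtype=object),
        freqs=np.arange(shape[0], dtype=float) + 1.0,
    )
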