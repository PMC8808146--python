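"""HDF5 containers for records and sample stores, plus tabular text I/O.

Records:   /signal (channels x samples), attrs sampling_rate, subject_id,
           /seizure_intervals (n x 2 seconds).
Samples:   /x (n, ch, freq, time), /y, /labeled, /segment_start, /source,
           /freqs.
Prediction streams and result tables are plain delimited text (CSV).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .evaluation import EvalResult
from .preprocessing import SampleSet
from .synthetic import EegRecord

__all__ = [
    "save_record", "load_record", "load_record_edf",
    "save_samples", "load_samples",
    "save_prediction_stream", "load_prediction_stream",
    "results_table",
]


def save_record(path: str | Path, record: EegRecord) -> None:
    record.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=record.signal, compression="gzip")
        f.create_dataset("seizure_intervals",
                         data=np.asarray(record.seizure_intervals, dtype=float)
                         .reshape(-1, 2))
        f.attrs["sampling_rate"] = record.sampling_rate
        f.attrs["subject_id"] = record.subject_id


def load_record(path: str | Path) -> EegRecord:
    with h5py.File(path, "r") as f:
        rec = EegRecord(
            signal=f["signal"][...],
            sampling_rate=float(f.attrs["sampling_rate"]),
            seizure_intervals=[tuple(map(float, row))
                               for row in f["seizure_intervals"][...]],
            subject_id=str(f.attrs["subject_id"]),
        )
    rec.validate()
    return rec


def load_record_edf(path: str | Path,
                    seizure_intervals: list[tuple[float, float]],
                    subject_id: str = "") -> EegRecord:
    """Read a real EDF recording (requires mne); annotations are supplied by
    the caller since EDF seizure annotations are corpus-specific."""
    import mne  # optional dependency, only for real data

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EegRecord(
        signal=raw.get_data() * 1e6,  # volts -> microvolts
        sampling_rate=float(raw.info["sfreq"]),
        seizure_intervals=list(seizure_intervals),
        subject_id=subject_id or Path(path).stem,
    )


def save_samples(path: str | Path, samples: SampleSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("x", data=samples.x, compression="gzip")
        f.create_dataset("y", data=samples.y)
        f.create_dataset("labeled", data=samples.labeled)
        f.create_dataset("segment_start", data=samples.segment_start)
        f.create_dataset("source",
                         data=np.asarray([str(s) for s in samples.source],
                                         dtype=h5py.string_dtype()))
        f.create_dataset("freqs", data=samples.freqs)


def load_samples(path: str | Path) -> SampleSet:
    with h5py.File(path, "r") as f:
        return SampleSet(
            x=f["x"][...],
            y=f["y"][...],
            labeled=f["labeled"][...].astype(bool),
            segment_start=f["segment_start"][...],
            source=np.asarray([s.decode() if isinstance(s, bytes) else str(s)
                               for s in f["source"][...]], dtype=object),
            freqs=f["freqs"][...],
        )


def save_prediction_stream(path: str | Path, times: np.ndarray,
                           states: np.ndarray) -> None:
    pd.DataFrame({"time_s": times, "preictal": np.asarray(states).astype(int)}) \
        .to_csv(path, index=False)


def load_prediction_stream(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(float), df["preictal"].to_numpy(int)


def results_table(results: dict[str, EvalResult]) -> pd.DataFrame:
    """Per-recording results as a table mirroring the usual reporting columns."""
    rows = []
    for name, r in results.items():
        rows.append({
            "recording": name, "TP": r.tp, "FN": r.fn, "FP": r.fp,
            "interictal_hours": r.interictal_hours,
            "sensitivity_pct": r.sensitivity,
            "FPR_per_hour": r.fpr_per_hour,
            "p_value": r.p_value,
        })
    return pd.DataFrame(rows)
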