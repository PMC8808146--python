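"""Leave-one-seizure-recording-out partitioning.

A subject with N evaluable seizures yields N "seizure recordings": the
interictal samples are split chronologically into N contiguous near-equal
parts and part j is paired with seizure j's preictal samples (chronological
pairing).  Each recording serves once as the test set; of the rest, one is
drawn as validation, ``n_labeled`` keep their labels, and the remainder is
used unlabeled — the semisupervised setting requires N - 2 - n_labeled > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import SampleSet

__all__ = ["SeizureRecording", "FoldSpec", "build_recordings", "make_folds"]


@dataclass
class SeizureRecording:
    """One seizure's preictal samples plus one contiguous interictal part."""

    recording_id: str
    preictal_idx: np.ndarray   # indices into the subject SampleSet
    interictal_idx: np.ndarray
    onset: float               # seizure onset time, seconds
    interictal_span: tuple[float, float]  # [first, last+segment) in seconds


@dataclass
class FoldSpec:
    """Role assignment of recordings for one cross-validation fold."""

    test: str
    validation: str
    labeled: list[str]
    unlabeled: list[str]
    seed: int

    def all_ids(self) -> list[str]:
        return [self.test, self.validation, *self.labeled, *self.unlabeled]


def build_recordings(
    samples: SampleSet,
    seizure_onsets: list[float],
    segment_length: float = 30.0,
) -> list[SeizureRecording]:
    """Assemble the N seizure recordings of a subject.

    ``samples`` holds the subject's non-overlapping preictal and interictal
    segments; ``seizure_onsets`` are the evaluable onsets (N = their count,
    must be >= 4 to leave room for test, validation, labeled and unlabeled
    roles).  Interictal samples are split chronologically into N contiguous
    parts whose sizes differ by at most one (earlier parts take the
    remainder).
    """
    onsets = sorted(float(o) for o in seizure_onsets)
    n = len(onsets)
    if n < 4:
        raise ValueError(
            f"subject has {n} evaluable seizures; at least 4 are required "
            "for the leave-one-out semisupervised design"
        )
    y = np.asarray(samples.y)
    order = np.argsort(samples.segment_start, kind="stable")
    inter = order[y[order] == 0]
    pre = order[y[order] == 1]
    if len(inter) < n:
        raise ValueError(f"only {len(inter)} interictal samples for N={n} parts")

    # contiguous chronological split, remainder to the earliest parts
    base, rem = divmod(len(inter), n)
    sizes = [base + (1 if j < rem else 0) for j in range(n)]
    parts, pos = [], 0
    for s in sizes:
        parts.append(inter[pos : pos + s])
        pos += s

    recordings = []
    starts = samples.segment_start
    for j, onset in enumerate(onsets):
        pre_j = pre[(starts[pre] >= onset - 1800.0 - 1e-6) & (starts[pre] < onset)]
        span = (float(starts[parts[j]].min()),
                float(starts[parts[j]].max() + segment_length))
        recordings.append(SeizureRecording(
            recording_id=f"rec{j}",
            preictal_idx=pre_j,
            interictal_idx=parts[j],
            onset=onset,
            interictal_span=span,
        ))
    return recordings


def make_folds(
    recordings: list[SeizureRecording], n_labeled: int, seed: int
) -> list[FoldSpec]:
    """The N leave-one-out folds with random validation/labeled assignment.

    Fold i takes recording i as test; validation and the ``n_labeled``
    labeled recordings are drawn uniformly from the rest, reproducibly from
    ``seed``.  Requires N - 2 - n_labeled > 0 so the unlabeled set is
    nonempty.
    """
    n = len(recordings)
    if n - 2 - n_labeled <= 0:
        raise ValueError(
            f"need N - 2 - n_labeled > 0 for a nonempty unlabeled set; "
            f"got N={n}, n_labeled={n_labeled} (minimum N is {n_labeled + 3})"
        )
    ids = [r.recording_id for r in recordings]
    folds = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        rest = [r for r in ids if r != ids[i]]
        rng.shuffle(rest)
        folds.append(FoldSpec(
            test=ids[i],
            validation=rest[0],
            labeled=sorted(rest[1 : 1 + n_labeled]),
            unlabeled=sorted(rest[1 + n_labeled :]),
            seed=seed,
        ))
    return folds
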