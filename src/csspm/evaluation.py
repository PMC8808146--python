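"""Alarms and seizure-prediction metrics.

Per-segment binary decisions become alarms through a k-of-n rule with a
refractory period; alarms are scored against seizure onsets under the
SOP/SPH convention (an alarm at time a predicts an onset inside
``[a + SPH, a + SPH + SOP]``, both ends closed); sensitivity, false
prediction rate and a random-predictor p-value summarize a test recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "AlarmConfig",
    "ScoringConfig",
    "EvalResult",
    "generate_alarms",
    "score_alarms",
    "random_predictor_p",
    "aggregate",
]


@dataclass
class AlarmConfig:
    """k-of-n alarm rule: fire when >= k of the last n segment decisions are
    preictal, at most once per refractory period."""

    k: int = 8
    n: int = 10
    refractory_s: float = 1800.0
    segment_s: float = 30.0

    def validate(self) -> None:
        if not (1 <= self.k <= self.n):
            raise ValueError("need 1 <= k <= n")
        if self.refractory_s < 0 or self.segment_s <= 0:
            raise ValueError("durations must be positive")


@dataclass
class ScoringConfig:
    """SOP/SPH evaluation windows (defaults: SOP 30 min, SPH 5 min)."""

    sop_s: float = 1800.0
    sph_s: float = 300.0

    def validate(self) -> None:
        if self.sop_s <= 0 or self.sph_s <= 0:
            raise ValueError("SOP and SPH must be positive")


@dataclass
class EvalResult:
    """Per-recording (or per-subject) seizure-prediction scores."""

    tp: int
    fn: int
    fp: int
    interictal_hours: float
    sensitivity: float     # percent
    fpr_per_hour: float
    p_value: float
    n_seizures: int


def generate_alarms(
    times: np.ndarray, states: np.ndarray, cfg: AlarmConfig
) -> list[float]:
    """Run the k-of-n rule over a time-ordered per-segment decision stream.

    ``times`` are segment decision timestamps (one per ``segment_s``, strictly
    increasing), ``states`` the binary preictal decisions.  An alarm is
    emitted at the first segment whose trailing window of n decisions holds
    >= k preictal states, provided the refractory period has elapsed since
    the previous alarm; the first n - 1 segments cannot trigger.
    """
    cfg.validate()
    times = np.asarray(times, dtype=float)
    states = np.asarray(states).astype(int)
    if times.shape != states.shape:
        raise ValueError("times and states must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("prediction stream must be strictly time-ordered")
    alarms: list[float] = []
    last = -np.inf
    running = np.concatenate([[0], np.cumsum(states)])
    for i in range(cfg.n - 1, len(states)):
        if running[i + 1] - running[i + 1 - cfg.n] >= cfg.k:
            if times[i] - last >= cfg.refractory_s:
                alarms.append(float(times[i]))
                last = times[i]
    return alarms


def score_alarms(
    alarms: list[float],
    seizure_onsets: list[float],
    cfg: ScoringConfig,
    interictal_hours: float,
) -> EvalResult:
    """Score alarms against onsets under SOP/SPH.

    A seizure is predicted (TP) if some alarm a satisfies
    ``a + SPH <= onset <= a + SPH + SOP``; pairing is greedy
    earliest-alarm-to-earliest-seizure, each alarm claiming at most one
    seizure.  Unclaimed alarms are false alarms; FPR divides them by the
    recording's interictal hours.
    """
    cfg.validate()
    alarms = sorted(float(a) for a in alarms)
    onsets = sorted(float(o) for o in seizure_onsets)
    used = [False] * len(alarms)
    tp = 0
    for onset in onsets:
        for j, a in enumerate(alarms):
            if used[j]:
                continue
            if a + cfg.sph_s <= onset <= a + cfg.sph_s + cfg.sop_s:
                used[j] = True
                tp += 1
                break
    fn = len(onsets) - tp
    fp = used.count(False)
    if interictal_hours <= 0:
        if fp > 0:
            raise ValueError("false alarms with zero interictal time")
        fpr = 0.0
    else:
        fpr = fp / interictal_hours
    sens = 100.0 * tp / len(onsets) if onsets else float("nan")
    p = random_predictor_p(fpr, cfg.sop_s, tp, len(onsets)) if onsets else float("nan")
    return EvalResult(
        tp=tp, fn=fn, fp=fp, interictal_hours=float(interictal_hours),
        sensitivity=sens, fpr_per_hour=fpr, p_value=p, n_seizures=len(onsets),
    )


def random_predictor_p(
    fpr_per_hour: float, sop_s: float, n_predicted: int, n_seizures: int
) -> float:
    """Probability that a Poisson random predictor with the same FPR predicts
    at least ``n_predicted`` of ``n_seizures`` seizures.

    Per-seizure hit probability prob = 1 - exp(-FPR * SOP) with SOP in hours;
    the p-value is the binomial upper tail sum_{i >= k} C(K, i) prob^i
    (1 - prob)^(K - i).
    """
    if fpr_per_hour < 0 or sop_s < 0 or n_predicted < 0 or n_seizures < 0:
        raise ValueError("inputs must be nonnegative")
    if n_predicted > n_seizures:
        raise ValueError("cannot predict more seizures than occurred")
    if n_predicted == 0:
        return 1.0
    prob = 1.0 - np.exp(-fpr_per_hour * sop_s / 3600.0)
    return float(binom.sf(n_predicted - 1, n_seizures, prob))


def aggregate(per_fold_runs: list[list[EvalResult]]) -> dict:
    """Subject summary over folds and repeated runs.

    ``per_fold_runs[j]`` holds the repeated runs of fold j.  For each metric
    the per-fold mean and sample standard deviation across runs are computed
    first, then averaged unweighted across folds.  A single run per fold
    reports a standard deviation of 0 with a warning.
    """
    if not per_fold_runs or any(len(runs) == 0 for runs in per_fold_runs):
        raise ValueError("need at least one run per fold")
    if any(len(runs) < 2 for runs in per_fold_runs):
        warnings.warn("single run per fold: standard deviations reported as 0",
                      stacklevel=2)

    def stat(get):
        fold_means = [float(np.mean([get(r) for r in runs])) for runs in per_fold_runs]
        fold_stds = [
            float(np.std([get(r) for r in runs], ddof=1)) if len(runs) > 1 else 0.0
            for runs in per_fold_runs
        ]
        return float(np.mean(fold_means)), float(np.mean(fold_stds))

    out = {}
    for name, get in [("sensitivity", lambda r: r.sensitivity),
                      ("fpr_per_hour", lambda r: r.fpr_per_hour),
                      ("p_value", lambda r: r.p_value)]:
        mean, std = stat(get)
        out[f"{name}_mean"] = mean
        out[f"{name}_std"] = std
    out["n_folds"] = len(per_fold_runs)
    out["runs_per_fold"] = [len(r) for r in per_fold_runs]
    return out
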