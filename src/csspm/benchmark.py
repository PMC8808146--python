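"""End-to-end synthetic benchmark: semisupervised vs supervised arms.

A desk-scale study mirroring the semisupervised comparison design: one
synthetic subject with five seizures, leave-one-seizure-recording-out folds
with a single labeled training recording, and four training arms on identical
folds and seeds —

  csspm            : consistency regularization with unlabeled data
  baseline         : plain supervised training on the labeled recording only
  no_unlabeled     : csspm with the unlabeled recordings removed
  no_augmentation  : csspm with the Gaussian augmentation disabled (sigma=0)

Each arm reports held-out segment accuracy plus alarm-level sensitivity and
false prediction rate on the test recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import preprocessing as pp
from .evaluation import AlarmConfig, ScoringConfig, generate_alarms, score_alarms
from .network import ModelConfig
from .partitioning import build_recordings, make_folds
from .preprocessing import LabelingRules, SampleSet, StftConfig
from .synthetic import SyntheticConfig, generate_record
from .trainer import CsspmClassifier, FitResult, TrainConfig

__all__ = ["BenchmarkConfig", "run_benchmark", "prepare_subject", "ARMS"]

ARMS = ("csspm", "baseline", "no_unlabeled", "no_augmentation")


def _default_synthetic() -> SyntheticConfig:
    # five evaluable seizures, 8 h record at desk scale
    return SyntheticConfig(
        n_channels=4,
        sampling_rate=64.0,
        duration=28830.0,
        seizure_onsets=[5400.0, 10800.0, 16200.0, 21600.0, 27000.0],
        seizure_durations=[30.0] * 5,
        preictal_band=(4.0, 8.0),
        preictal_power_gain=2.0,
        background_spectrum_exponent=1.0,
        seed=0,
    )


def _default_rules() -> LabelingRules:
    # desk-scale interictal margin (30 min instead of 4 h) so an 8 h record
    # contains usable interictal stretches between seizures
    return LabelingRules(interictal_margin=1800.0, min_leading_seizures=4)


def _default_stft() -> StftConfig:
    # reduced spectrogram: 1-s window, no overlap -> 32 x 30 images at 64 Hz
    return StftConfig(stft_window=64, stft_overlap=0.0)


def _default_train() -> TrainConfig:
    # shortened schedule for the reduced problem size; ramp shapes preserved
    return TrainConfig(max_epochs=20, ramp_tau=14.0, rampdown_length=8)


@dataclass
class BenchmarkConfig:
    """Study conditions of the synthetic benchmark (see module docstring)."""

    synthetic: SyntheticConfig = field(default_factory=_default_synthetic)
    rules: LabelingRules = field(default_factory=_default_rules)
    stft: StftConfig = field(default_factory=_default_stft)
    model: ModelConfig | None = None
    train: TrainConfig = field(default_factory=_default_train)
    alarm: AlarmConfig = field(default_factory=AlarmConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    n_labeled: int = 1
    interictal_train_stride: float = 45.0
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])
    arms: tuple[str, ...] = ARMS


def prepare_subject(cfg: BenchmarkConfig, seed: int):
    """Generate one synthetic subject and its fold ingredients.

    Returns ``(eval_set, train_set, recordings, onsets)``: an evaluation-grade
    sample set (non-overlapping 30-s stride, used for test and validation
    roles), a training-grade set (strided interictal, overlap-balanced
    preictal) aligned to the same recordings, the N seizure recordings built
    on the evaluation-grade set, and the evaluable onsets.
    """
    synth = replace(cfg.synthetic, seed=seed)
    record = generate_record(synth)
    periods = pp.label_periods(record, cfg.rules)
    onsets = [o for o, _ in pp.evaluable_seizures(record, cfg.rules)]

    seg = cfg.stft.segment_length
    eval_set = pp.segment_and_stft(record, periods, cfg.stft, stride_s=seg)

    inter_train = pp.segment_and_stft(record, periods, cfg.stft,
                                      stride_s=cfg.interictal_train_stride,
                                      states=(pp.INTERICTAL,))
    pre_total = sum(b - a for (a, b), s in periods if s == pp.PREICTAL)
    n_pre_intervals = sum(1 for _, s in periods if s == pp.PREICTAL)
    balance = pp.compute_balance_stride(pre_total, len(inter_train), cfg.stft,
                                        n_intervals=n_pre_intervals)
    pre_train = pp.segment_and_stft(record, periods, cfg.stft,
                                    stride_s=balance.stride_s,
                                    states=(pp.PREICTAL,))
    train_set = SampleSet.concatenate([inter_train, pre_train])

    recordings = build_recordings(eval_set, onsets, segment_length=seg)
    return eval_set, train_set, recordings, onsets


def _assign(train_set: SampleSet, eval_set: SampleSet, recordings, fold):
    """Map samples to fold roles by recording time spans (training-grade set
    for training roles, evaluation-grade for validation and test)."""
    by_id = {r.recording_id: r for r in recordings}

    def train_idx(rec):
        starts = train_set.segment_start
        y = train_set.y
        a, b = rec.interictal_span
        inter = (y == 0) & (starts >= a - 1e-6) & (starts < b - 1e-6)
        pre = (y == 1) & (starts >= rec.onset - 1800.0 - 1e-6) & (starts < rec.onset)
        return np.where(inter | pre)[0]

    labeled_parts = [train_set.subset(train_idx(by_id[r])) for r in fold.labeled]
    unlabeled_parts = [train_set.subset(train_idx(by_id[r])).as_unlabeled()
                       for r in fold.unlabeled]
    train = SampleSet.concatenate(labeled_parts + unlabeled_parts)

    val_rec = by_id[fold.validation]
    val = eval_set.subset(np.concatenate([val_rec.interictal_idx,
                                          val_rec.preictal_idx]))
    test_rec = by_id[fold.test]
    test = eval_set.subset(np.concatenate([test_rec.interictal_idx,
                                           test_rec.preictal_idx]))
    return train, val, test, test_rec


def _evaluate(result: FitResult, test: SampleSet, test_rec, cfg: BenchmarkConfig):
    order = np.argsort(test.segment_start, kind="stable")
    x = test.x[order]
    y = test.y[order]
    pred = result.predict(x)
    acc = float((pred == y).mean())
    times = test.segment_start[order] + cfg.stft.segment_length
    alarms = generate_alarms(times, pred, cfg.alarm)
    span = test_rec.interictal_span
    hours = (span[1] - span[0]) / 3600.0
    ev = score_alarms(alarms, [test_rec.onset], cfg.scoring, hours)
    return {"segment_accuracy": acc, "sensitivity": ev.sensitivity,
            "fpr_per_hour": ev.fpr_per_hour, "n_alarms": len(alarms)}


def _fit_arm(arm: str, train: SampleSet, val: SampleSet,
             model_cfg: ModelConfig, tcfg: TrainConfig) -> FitResult:
    if arm == "baseline":
        lab = train.subset(np.where(train.labeled)[0])
        clf = CsspmClassifier.from_sample_sets(lab, val, model_cfg, tcfg)
        return clf.fit(supervised_only=True)
    if arm == "no_unlabeled":
        lab = train.subset(np.where(train.labeled)[0])
        clf = CsspmClassifier.from_sample_sets(lab, val, model_cfg, tcfg)
        return clf.fit()
    if arm == "no_augmentation":
        clf = CsspmClassifier.from_sample_sets(
            train, val, model_cfg, replace(tcfg, noise_sigma=0.0))
        return clf.fit()
    if arm == "csspm":
        clf = CsspmClassifier.from_sample_sets(train, val, model_cfg, tcfg)
        return clf.fit()
    raise ValueError(f"unknown arm {arm!r}")


def run_benchmark(cfg: BenchmarkConfig | None = None, seed: int = 0) -> dict:
    """Run all arms over ``cfg.seeds`` (offset by ``seed``) and aggregate.

    Each benchmark seed generates its own subject and fold set; the fold used
    is rotated with the seed so the N folds are covered across seeds.  All
    arms share the subject, fold manifest and training seed.
    """
    cfg = cfg or BenchmarkConfig()
    report: dict = {"arms": {a: {"runs": []} for a in cfg.arms},
                    "seeds": [s + seed for s in cfg.seeds]}
    for s in report["seeds"]:
        eval_set, train_set, recordings, onsets = prepare_subject(cfg, s)
        folds = make_folds(recordings, cfg.n_labeled, seed=s)
        fold = folds[s % len(folds)]
        train, val, test, test_rec = _assign(train_set, eval_set, recordings, fold)
        model_cfg = cfg.model or ModelConfig(n_channels=train.x.shape[1])
        tcfg = replace(cfg.train, seed=s)
        fold_manifest = {"test": fold.test, "validation": fold.validation,
                         "labeled": fold.labeled, "unlabeled": fold.unlabeled}
        for arm in cfg.arms:
            result = _fit_arm(arm, train, val, model_cfg, tcfg)
            run = _evaluate(result, test, test_rec, cfg)
            run.update({"seed": s, "fold": fold_manifest,
                        "best_epoch": result.best_epoch,
                        "best_val_accuracy": result.best_val_accuracy})
            report["arms"][arm]["runs"].append(run)
    for arm, d in report["arms"].items():
        accs = [r["segment_accuracy"] for r in d["runs"]]
        d["mean_segment_accuracy"] = float(np.mean(accs))
        d["std_segment_accuracy"] = float(np.std(accs))
        d["mean_sensitivity"] = float(np.mean([r["sensitivity"] for r in d["runs"]]))
        d["mean_fpr_per_hour"] = float(np.mean([r["fpr_per_hour"] for r in d["runs"]]))
    return report
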