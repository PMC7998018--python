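"""Weighted two-stream ensemble, the evaluation metric suite, and the
end-to-end pipeline.

The ensemble score is w * temporal + (1 - w) * spatial with w traversed
over 0.00, 0.01, ..., 1.00; the reported weight is the one maximizing
validation accuracy (smallest w on ties).  The same machinery serves two
tasks that differ only in the label column: predicting blastocyst
formation ("blastocyst") and predicting usable-blastocyst quality
("usable").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import spatial as sp
from . import temporal as tp
from .counting import StageClassifier, StageClassifierConfig, classify_stages, train_stage_classifier
from .synthetic import generate_dataset, load_dataset
from .videoprep import (
    FrameClassifier,
    classify_one_cell,
    correct_sequence,
    detect_pn,
    locate_pnf,
    screen_video,
    train_one_cell_model,
    train_pn_model,
)

__all__ = [
    "TASKS",
    "EnsembleWeight",
    "MetricsReport",
    "PipelineConfig",
    "PreparedData",
    "PipelineResult",
    "ensemble_score",
    "classify",
    "search_weight",
    "compute_metrics",
    "roc_auc",
    "split_indices",
    "train_preparation_models",
    "prepare_dataset",
    "run_task",
    "run_pipeline",
]

TASKS = ("blastocyst", "usable")
_WEIGHT_GRID = np.round(np.arange(101) / 100.0, 2)


@dataclass(frozen=True)
class EnsembleWeight:
    """Temporal-stream weight on the 0.01 grid; spatial gets 1 - w."""

    w_temporal: float

    def __post_init__(self):
        w = self.w_temporal
        if not (0.0 <= w <= 1.0) or abs(round(w * 100) - w * 100) > 1e-9:
            raise ValueError("w_temporal must lie on the 0.00..1.00 grid at 0.01 steps")

    @property
    def w_spatial(self) -> float:
        return round(1.0 - self.w_temporal, 2)


def ensemble_score(pt: float, ps: float, w: EnsembleWeight | float) -> float:
    """w * temporal + (1 - w) * spatial."""
    if isinstance(w, EnsembleWeight):
        w = w.w_temporal
    pt, ps = float(pt), float(ps)
    if not (0.0 <= pt <= 1.0 and 0.0 <= ps <= 1.0):
        raise ValueError("stream scores must be probabilities in [0, 1]")
    return w * pt + (1.0 - w) * ps


def classify(score: float, threshold: float = 0.5) -> int:
    """Binary call: 1 iff score >= threshold."""
    if not 0.0 <= score <= 1.0:
        raise ValueError("score must be in [0, 1]")
    return int(score >= threshold)


def search_weight(
    temporal_scores: np.ndarray,
    spatial_scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> tuple[EnsembleWeight, float]:
    """Traverse the 101-point weight grid and return the
    accuracy-maximizing weight (smallest on ties) with its accuracy."""
    pt = np.asarray(temporal_scores, dtype=float)
    ps = np.asarray(spatial_scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(pt) == 0 or len(pt) != len(ps) or len(pt) != len(y):
        raise ValueError("scores and labels must be non-empty and equal length")
    ens = _WEIGHT_GRID[:, None] * pt[None, :] + (1.0 - _WEIGHT_GRID[:, None]) * ps[None, :]
    acc = ((ens >= threshold).astype(int) == y[None, :]).mean(axis=1)
    best = int(np.argmax(acc))  # argmax takes the first (smallest-w) maximum
    return EnsembleWeight(float(_WEIGHT_GRID[best])), float(acc[best])


@dataclass
class MetricsReport:
    """Counts plus the standard ratio metrics; a ratio with zero
    denominator is None (undefined), never silently 0."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "tn", "fp", "fn", "sensitivity", "specificity", "ppv", "npv",
                 "accuracy", "auc")}


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(calls: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """Sensitivity = TP/P, specificity = TN/N, PPV = TP/(predicted
    positive), NPV = TN/(predicted negative), accuracy = (TP+TN)/n."""
    calls = np.asarray(calls, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if calls.shape != labels.shape or calls.ndim != 1 or len(calls) == 0:
        raise ValueError("calls and labels must be non-empty 1-D arrays of equal length")
    tp = int(np.sum((calls == 1) & (labels == 1)))
    tn = int(np.sum((calls == 0) & (labels == 0)))
    fp = int(np.sum((calls == 1) & (labels == 0)))
    fn = int(np.sum((calls == 0) & (labels == 1)))
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=(tp + tn) / len(calls),
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Threshold-swept ROC points and the area under the curve.

    The trapezoidal area over the swept thresholds equals the
    Mann-Whitney pair statistic with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC/AUC needs both outcome classes")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    points = pd.DataFrame({"threshold": thr, "fpr": fpr, "sensitivity": tpr})
    return points, float(_sk_auc(fpr, tpr))


def split_indices(n: int, val_fraction: float = 0.2, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled train/validation split with n_val = round(val_fraction * n)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    return np.sort(order[n_val:]), np.sort(order[:n_val])


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end run needs beyond the dataset itself."""

    counting: StageClassifierConfig = field(default_factory=StageClassifierConfig)
    temporal: tp.TemporalModelConfig = field(default_factory=tp.TemporalModelConfig)
    spatial: sp.SpatialModelConfig = field(default_factory=sp.SpatialModelConfig)
    #: videos in the auxiliary annotation set used to train frame models
    n_annotation_videos: int = 60
    #: labeled frames sampled per annotation video (stage-stratified)
    frames_per_annotation_video: int = 40
    val_fraction: float = 0.2
    threshold: float = 0.5


@dataclass
class PreparedData:
    """Label-independent products of the preparation + feature stage."""

    video_ids: list[str]
    windows: list[tp.TemporalWindow]  # stage tags, label unset
    features: list[sp.CheckpointFeatureMatrix]
    labels: pd.DataFrame  # blastocyst, usable for retained videos
    pnf_estimates: list[int]
    screening: pd.DataFrame  # per input video: retain flag + reason
    one_cell_model: FrameClassifier
    pn_model: FrameClassifier
    stage_model: StageClassifier


@dataclass
class PipelineResult:
    task: str
    weight: EnsembleWeight
    metrics: MetricsReport
    temporal_metrics: MetricsReport
    spatial_metrics: MetricsReport
    records: pd.DataFrame  # per validation embryo: scores, call, label
    n_train: int
    n_val: int


def sample_annotation_frames(
    dataset, per_video: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample stage-stratified labeled frames from every video of an
    annotation dataset; returns (frames, stages, pn, one_cell)."""
    frames, stages, pn = [], [], []
    for i in range(dataset.n):
        video, truth = dataset.video(i)
        idx = []
        present = np.unique(truth.stages)
        per_stage = max(1, per_video // len(present))
        for s in present:
            cand = np.flatnonzero(truth.stages == s)
            idx.append(rng.choice(cand, size=min(per_stage, len(cand)), replace=False))
        # make sure frames on both sides of PNF are seen by the PN model
        ones = np.flatnonzero((truth.stages == 1) & (truth.pn == 1))
        zeros = np.flatnonzero((truth.stages == 1) & (truth.pn == 0))
        for cand in (ones, zeros):
            if len(cand):
                idx.append(rng.choice(cand, size=min(4, len(cand)), replace=False))
        idx = np.unique(np.concatenate(idx))
        frames.append(video.frames[idx])
        stages.append(truth.stages[idx])
        pn.append(truth.pn[idx])
    frames = np.concatenate(frames)
    stages = np.concatenate(stages)
    pn = np.concatenate(pn)
    return frames, stages, pn, (stages == 1).astype(np.int8)


def train_preparation_models(
    annotation_dataset, config: PipelineConfig, seed: int
) -> tuple[FrameClassifier, FrameClassifier, StageClassifier]:
    """Train the 1-cell, PN and cell-stage frame models on an annotation
    dataset (kept separate from the prediction analysis set)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    frames, stages, pn, one_cell = sample_annotation_frames(
        annotation_dataset, config.frames_per_annotation_video, rng
    )
    one_cell_model = train_one_cell_model(frames, one_cell, seed=seed + 1)
    mask = one_cell == 1
    pn_model = train_pn_model(frames[mask], pn[mask], seed=seed + 2)
    stage_model = train_stage_classifier(frames, stages,
                                         replace(config.counting, seed=seed + 3))
    return one_cell_model, pn_model, stage_model


def prepare_dataset(
    dataset, config: PipelineConfig | None = None, seed: int = 0,
    annotation_dataset=None,
) -> PreparedData:
    """Run preparation and feature extraction over an analysis dataset.

    Steps per video: classify 1-cell frames, estimate PN presence inside
    the 1-cell stage, clean the PN sequence with the correction filter,
    locate PNF as the last remaining 1, screen (length and window
    feasibility), then — for retained videos — classify all frames into
    cell stages, cut the 600-frame temporal window and embed the 35
    checkpoint frames.  If no annotation dataset is supplied a synthetic
    one is generated from the dataset's own generator spec with a
    derived seed.
    """
    config = config or PipelineConfig()
    if annotation_dataset is None:
        if getattr(dataset, "spec", None) is None:
            raise ValueError("an annotation dataset is required when the analysis "
                             "dataset has no generator spec")
        ann_spec = replace(dataset.spec, n_videos=config.n_annotation_videos,
                           seed=dataset.spec.seed + 90001)
        annotation_dataset = generate_dataset(ann_spec)
    one_cell_model, pn_model, stage_model = train_preparation_models(
        annotation_dataset, config, seed
    )

    ids, windows, feats, pnfs, rows, screening = [], [], [], [], [], []
    for i in range(dataset.n):
        video, _ = dataset.video(i)
        one_cell = classify_one_cell(video, one_cell_model)
        pn_seq = detect_pn(video, one_cell, pn_model)
        pn_seq = correct_sequence(pn_seq)
        pnf = locate_pnf(pn_seq)
        decision = screen_video(video, pnf)
        screening.append(dict(video_id=video.video_id, retain=decision.retain,
                              reason=decision.reason,
                              pnf=pnf.frame if pnf.found else None))
        if not decision.retain:
            continue
        tags = classify_stages(video, stage_model)
        windows.append(tp.extract_temporal_window(tags, pnf.frame))
        feats.append(sp.embed_frames(sp.extract_checkpoint_frames(video, pnf.frame),
                                     stage_model, embryo_id=video.video_id))
        pnfs.append(pnf.frame)
        ids.append(video.video_id)
        rows.append(dict(video_id=video.video_id,
                         blastocyst=int(dataset.labels.blastocyst.iloc[i]),
                         usable=int(dataset.labels.usable.iloc[i])))
    if not rows:
        raise ValueError("no videos survived screening")
    return PreparedData(
        video_ids=ids, windows=windows, features=feats,
        labels=pd.DataFrame(rows), pnf_estimates=pnfs,
        screening=pd.DataFrame(screening),
        one_cell_model=one_cell_model, pn_model=pn_model, stage_model=stage_model,
    )


def run_task(
    prepared: PreparedData, task: str, config: PipelineConfig | None = None, seed: int = 0
) -> PipelineResult:
    """Train both streams on the 80% split, search the ensemble weight
    and report metrics on the 20% validation split for one task."""
    config = config or PipelineConfig()
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}, got {task!r}")
    y = prepared.labels[task].to_numpy(int)
    n = len(y)
    train_idx, val_idx = split_indices(n, config.val_fraction, seed=seed + 17)

    train_windows = [
        replace_window_label(prepared.windows[i], int(y[i])) for i in train_idx
    ]
    t_model = tp.train_temporal(train_windows, replace(config.temporal, seed=seed + 31))
    s_model = sp.train_spatial([prepared.features[i] for i in train_idx], y[train_idx],
                               replace(config.spatial, seed=seed + 37))

    val_windows = [prepared.windows[i] for i in val_idx]
    pt = t_model.predict(val_windows)
    ps = s_model.predict_proba([prepared.features[i] for i in val_idx])
    yv = y[val_idx]
    weight, _ = search_weight(pt, ps, yv, threshold=config.threshold)
    ens = weight.w_temporal * pt + weight.w_spatial * ps
    calls = (ens >= config.threshold).astype(int)

    metrics = compute_metrics(calls, yv)
    metrics.auc = roc_auc(ens, yv)[1]
    t_metrics = compute_metrics((pt >= config.threshold).astype(int), yv)
    t_metrics.auc = roc_auc(pt, yv)[1]
    s_metrics = compute_metrics((ps >= config.threshold).astype(int), yv)
    s_metrics.auc = roc_auc(ps, yv)[1]

    records = pd.DataFrame(dict(
        embryo_id=[prepared.video_ids[i] for i in val_idx],
        temporal_score=pt, spatial_score=ps, ensemble_score=ens,
        call=calls, label=yv,
    ))
    return PipelineResult(task=task, weight=weight, metrics=metrics,
                          temporal_metrics=t_metrics, spatial_metrics=s_metrics,
                          records=records, n_train=len(train_idx), n_val=len(val_idx))


def replace_window_label(window: tp.TemporalWindow, label: int) -> tp.TemporalWindow:
    return tp.TemporalWindow(tags=window.tags, pnf=window.pnf, label=label)


def run_pipeline(
    dataset, task: str = "blastocyst", config: PipelineConfig | None = None, seed: int = 0
) -> PipelineResult:
    """End-to-end run on a dataset (a :class:`SyntheticDataset`, a
    written dataset directory, or anything with the same interface)."""
    if isinstance(dataset, (str,)) or hasattr(dataset, "__fspath__"):
        dataset = load_dataset(dataset)
    config = config or PipelineConfig()
    prepared = prepare_dataset(dataset, config, seed=seed)
    return run_task(prepared, task, config, seed=seed)
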