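"""Cell-stage counting: classify every frame into 1, 2, 3, 4 or >=5
cells and emit the per-frame tag sequence the temporal stream consumes.

Stage durations are heavily imbalanced (the 3-cell stage occupies only a
few percent of frames), so training uses a focal-loss objective with
inverse-frequency class weights by default, which keeps the rare stages
from being swamped by the abundant 1-cell frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import SoftmaxMLP, focal_loss
from .videoprep import EmbryoVideo, FrameClassifier, preprocess_frames

__all__ = [
    "STAGES",
    "StageTagSequence",
    "StageClassifierConfig",
    "StageClassifier",
    "focal_loss",
    "train_stage_classifier",
    "classify_stages",
    "stage_confusion",
]

#: the five cell-stage classes; 5 means ">=5 cells" (open-ended)
STAGES = (1, 2, 3, 4, 5)


@dataclass
class StageTagSequence:
    """Ordered (frame_number, stage) tags, one per frame."""

    frames: np.ndarray
    stages: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.stages = np.asarray(self.stages, dtype=np.int8)
        if self.frames.shape != self.stages.shape or self.frames.ndim != 1:
            raise ValueError("frames and stages must be matching 1-D arrays")
        if len(self.frames) and not np.array_equal(
            self.frames, np.arange(self.frames[0], self.frames[0] + len(self.frames))
        ):
            raise ValueError("frame numbers must be strictly increasing and contiguous")
        if not np.isin(self.stages, STAGES).all():
            raise ValueError("stages must be in {1, 2, 3, 4, 5}")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class StageClassifierConfig:
    backbone: str = "compact_mlp"  # pluggable; a DenseNet-class CNN drops in here
    hidden_dims: tuple[int, ...] = (1000,)  # penultimate width = embedding dim
    downsample: int = 2
    focal_gamma: float = 2.0
    class_weights: tuple[float, ...] | None = None  # None -> inverse frequency
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.class_weights is not None and any(w <= 0 for w in self.class_weights):
            raise ValueError("class_weights must be positive")


@dataclass
class StageClassifier(FrameClassifier):
    """Frame -> stage model; also serves as the shared embedding backbone
    (its penultimate activations are the per-frame spatial features)."""

    config: StageClassifierConfig = field(default_factory=StageClassifierConfig)

    def predict_stages(self, frames: np.ndarray) -> np.ndarray:
        return self.predict(frames) + 1  # class index 0..4 -> stage 1..5

    def save(self, path) -> None:
        self.mlp.save(path)

    @classmethod
    def load(cls, path, config: StageClassifierConfig | None = None) -> "StageClassifier":
        config = config or StageClassifierConfig()
        return cls(SoftmaxMLP.load(path), downsample=config.downsample,
                   task="cell_stage", config=config)


def train_stage_classifier(
    frames: np.ndarray, stages: np.ndarray, config: StageClassifierConfig | None = None
) -> StageClassifier:
    """Train the five-stage frame classifier with the focal loss.

    ``frames`` is an (n, H, W) stack of labeled frames with stages in
    {1..5}.  All five classes must be present; the error names any
    missing one.  Deterministic given the config seed.
    """
    config = config or StageClassifierConfig()
    if config.backbone != "compact_mlp":
        raise ValueError(f"unknown backbone {config.backbone!r}")
    stages = np.asarray(stages, dtype=int)
    present = set(np.unique(stages))
    missing = [s for s in STAGES if s not in present]
    if missing:
        raise ValueError(f"training data is missing cell stage(s): {missing}")
    y = stages - 1
    if config.class_weights is not None:
        weights = np.asarray(config.class_weights, dtype=float)
    else:
        counts = np.bincount(y, minlength=5).astype(float)
        weights = counts.sum() / (5.0 * counts)
    X = preprocess_frames(frames, config.downsample)
    mlp = SoftmaxMLP(X.shape[1], config.hidden_dims, 5, seed=config.seed)
    mlp.fit(X, y, epochs=config.epochs, batch_size=config.batch_size,
            lr=config.learning_rate, gamma=config.focal_gamma, class_weights=weights)
    return StageClassifier(mlp, downsample=config.downsample, task="cell_stage", config=config)


def classify_stages(video: EmbryoVideo, model: StageClassifier) -> StageTagSequence:
    """One (frame_number, stage) tag per frame, frames 0..n-1.

    No temporal smoothing or monotonicity constraint is applied; the
    correction happens downstream only for the binary PN sequence.
    """
    stages = model.predict_stages(video.frames)
    return StageTagSequence(frames=np.arange(len(video)), stages=stages)


def stage_confusion(
    predicted: StageTagSequence, truth: StageTagSequence
) -> tuple[np.ndarray, np.ndarray]:
    """5x5 confusion matrix (rows = true stage, columns = predicted) and
    per-class sensitivity = diagonal / row total (NaN for empty rows)."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth sequences differ in length")
    from sklearn.metrics import confusion_matrix

    cm = confusion_matrix(truth.stages, predicted.stages, labels=list(STAGES))
    row = cm.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row > 0, np.diag(cm) / row, np.nan)
    return cm, sens
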