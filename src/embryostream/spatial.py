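"""Spatial stream: checkpoint frame extraction, frame embeddings and a
gradient-boosted classifier over the ordered feature matrix.

Morphological assessment in the clinic happens at a handful of fixed
observation timings.  Mirroring that, seven frames are taken at each of
five PNF-anchored checkpoints — fertilization check (PNF-75..-69),
syngamy check (PNF-3..+3), early cleavage check (PNF+33..+39), day-2
assessment (PNF+249..+255) and day-3 assessment (PNF+493..+499) — for 35
frames per video.  Each frame is embedded by the shared image backbone
(D = 1000 features by default) and the ordered 35 x D matrix, flattened
row-major, feeds a gradient-boosted tree classifier.  Keeping only 35
frames deliberately limits model capacity relative to full videos.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lightgbm import LGBMClassifier

from .videoprep import EmbryoVideo, FrameClassifier

__all__ = [
    "CHECKPOINT_OFFSETS",
    "N_CHECKPOINT_FRAMES",
    "CheckpointFeatureMatrix",
    "SpatialModelConfig",
    "SpatialModel",
    "checkpoint_indices",
    "extract_checkpoint_frames",
    "embed_frames",
    "train_spatial",
    "predict_spatial",
]

#: inclusive frame-offset intervals relative to PNF, in clinical order
CHECKPOINT_OFFSETS = ((-75, -69), (-3, 3), (33, 39), (249, 255), (493, 499))
N_CHECKPOINT_FRAMES = sum(b - a + 1 for a, b in CHECKPOINT_OFFSETS)  # 35


def checkpoint_indices(pnf: int) -> np.ndarray:
    """The 35 ascending frame indices of the five observation windows."""
    if pnf < 75:
        raise ValueError(f"pnf must be >= 75 to place the fertilization check (got {pnf})")
    idx = np.concatenate([np.arange(pnf + a, pnf + b + 1) for a, b in CHECKPOINT_OFFSETS])
    return idx.astype(int)


def extract_checkpoint_frames(video: EmbryoVideo, pnf: int) -> np.ndarray:
    """The 35 checkpoint frames of a video as an (35, H, W) stack."""
    idx = checkpoint_indices(pnf)
    if idx[-1] >= len(video):
        raise ValueError("video too short for the day-3 assessment window")
    return video.frames[idx]


@dataclass
class CheckpointFeatureMatrix:
    """Ordered 35 x D embedding matrix for one embryo."""

    matrix: np.ndarray
    embryo_id: str = ""
    label: int | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != N_CHECKPOINT_FRAMES:
            raise ValueError(f"feature matrix must have exactly {N_CHECKPOINT_FRAMES} rows")


def embed_frames(frames: np.ndarray, backbone: FrameClassifier,
                 embryo_id: str = "", label: int | None = None) -> CheckpointFeatureMatrix:
    """Embed the 35 checkpoint frames, rows in checkpoint order."""
    frames = np.asarray(frames)
    if frames.shape[0] != N_CHECKPOINT_FRAMES:
        raise ValueError(f"expected {N_CHECKPOINT_FRAMES} frames, got {frames.shape[0]}")
    return CheckpointFeatureMatrix(backbone.embed(frames), embryo_id=embryo_id, label=label)


@dataclass(frozen=True)
class SpatialModelConfig:
    n_estimators: int = 60  # boosting rounds
    learning_rate: float = 0.1
    num_leaves: int = 15
    #: fraction of the 35 x D features each tree may see; with the wide,
    #: highly redundant embedding this is the standard p >> n regime
    feature_fraction: float = 0.15
    seed: int = 0


@dataclass
class SpatialModel:
    clf: LGBMClassifier
    n_features: int
    config: SpatialModelConfig

    def predict_proba(self, mats: list[CheckpointFeatureMatrix]) -> np.ndarray:
        X = _flatten(mats)
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper records synthetic feature names at
            # fit time; plain arrays at predict time are intentional here
            warnings.filterwarnings("ignore", message="X does not have valid feature names")
            return self.clf.predict_proba(X)[:, 1]


def _flatten(mats: list[CheckpointFeatureMatrix]) -> np.ndarray:
    # row-major: checkpoint order is the slow axis, as the matrices are stored
    return np.stack([m.matrix.reshape(-1) for m in mats])


def train_spatial(
    mats: list[CheckpointFeatureMatrix],
    labels: np.ndarray,
    config: SpatialModelConfig | None = None,
) -> SpatialModel:
    """Fit the gradient-boosted classifier on flattened feature matrices.

    Deterministic given the config seed; raises on single-class data.
    """
    config = config or SpatialModelConfig()
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data contains a single outcome class")
    X = _flatten(mats)
    clf = LGBMClassifier(
        n_estimators=config.n_estimators,
        learning_rate=config.learning_rate,
        num_leaves=config.num_leaves,
        feature_fraction=config.feature_fraction,
        deterministic=True,
        n_jobs=1,
        random_state=config.seed,
        verbose=-1,
    )
    clf.fit(X, labels)
    return SpatialModel(clf=clf, n_features=X.shape[1], config=config)


def predict_spatial(model: SpatialModel, features: CheckpointFeatureMatrix) -> float:
    """Positive-class probability for one embryo."""
    return float(model.predict_proba([features])[0])
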