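"""Temporal stream: PNF-anchored 600-frame stage windows and a recurrent
sequence classifier over them.

Each retained video contributes the stage tags of the 600 frames from
PNF-100 to PNF+499 (inclusive).  Anchoring on pronuclear fading removes
the systematic IVF/ICSI timing offset, so the sequence model sees
morphokinetics — when and for how long the embryo sits in each cell
stage — rather than absolute recording time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counting import STAGES, StageTagSequence
from .nn import LSTMBinaryClassifier
from .videoprep import PNF_WINDOW_AFTER, PNF_WINDOW_BEFORE

__all__ = [
    "WINDOW_LENGTH",
    "TemporalWindow",
    "TemporalModelConfig",
    "TemporalModel",
    "extract_temporal_window",
    "encode_windows",
    "train_temporal",
    "predict_temporal",
]

WINDOW_LENGTH = PNF_WINDOW_BEFORE + PNF_WINDOW_AFTER + 1  # 600


@dataclass
class TemporalWindow:
    """600 stage values covering frames pnf-100 .. pnf+499."""

    tags: np.ndarray
    pnf: int
    label: int | None = None

    def __post_init__(self):
        self.tags = np.asarray(self.tags, dtype=np.int8)
        if self.tags.shape != (WINDOW_LENGTH,):
            raise ValueError(f"a temporal window must hold exactly {WINDOW_LENGTH} stage values")
        if not np.isin(self.tags, STAGES).all():
            raise ValueError("stage values must be in {1, 2, 3, 4, 5}")


@dataclass(frozen=True)
class TemporalModelConfig:
    hidden_size: int = 32
    layers: int = 1
    encoding: str = "one_hot_stage"  # or "integer_stage"
    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 8e-3
    seed: int = 0

    def __post_init__(self):
        if self.hidden_size < 1 or self.layers != 1:
            raise ValueError("hidden_size must be positive; only a single recurrent layer is supported")
        if self.encoding not in ("one_hot_stage", "integer_stage"):
            raise ValueError(f"unknown encoding {self.encoding!r}")


def extract_temporal_window(
    tags: StageTagSequence, pnf: int, label: int | None = None
) -> TemporalWindow:
    """The 600 stage values at frames pnf-100 .. pnf+499, order preserved.

    The tag sequence must start at frame 0 and cover the whole window
    (screening guarantees this for retained videos).
    """
    if len(tags) == 0 or tags.frames[0] != 0:
        raise ValueError("tag sequence must start at frame 0")
    start, stop = pnf - PNF_WINDOW_BEFORE, pnf + PNF_WINDOW_AFTER
    if start < 0 or stop >= len(tags):
        raise ValueError(
            f"window pnf-{PNF_WINDOW_BEFORE}..pnf+{PNF_WINDOW_AFTER} out of range for "
            f"pnf={pnf} and {len(tags)} frames"
        )
    return TemporalWindow(tags=tags.stages[start : stop + 1].copy(), pnf=int(pnf), label=label)


def encode_windows(windows: list[TemporalWindow], encoding: str) -> np.ndarray:
    """Stage tags -> model input array (n, 600, d).

    One-hot encoding (default) gives d=5; the frame number is implicit
    in the sequence position after PNF alignment.  Integer encoding
    scales the stage to [0, 1] with d=1.
    """
    stages = np.stack([w.tags for w in windows]).astype(int)
    if encoding == "one_hot_stage":
        return np.eye(5)[stages - 1]
    if encoding == "integer_stage":
        return (stages[..., None] - 1) / 4.0
    raise ValueError(f"unknown encoding {encoding!r}")


@dataclass
class TemporalModel:
    net: LSTMBinaryClassifier
    config: TemporalModelConfig
    #: refitted logistic readout over the recurrent features (see
    #: train_temporal); falls back to the net's own readout when None
    head: object | None = None

    def predict(self, windows: list[TemporalWindow]) -> np.ndarray:
        X = encode_windows(windows, self.config.encoding)
        if self.head is None:
            return self.net.predict_proba(X)
        return self.head.predict_proba(self.net.features(X))[:, 1]


def train_temporal(
    windows: list[TemporalWindow], config: TemporalModelConfig | None = None
) -> TemporalModel:
    """Train the recurrent sequence classifier on labeled windows.

    Deterministic given the config seed; raises if only one outcome
    class is present.
    """
    config = config or TemporalModelConfig()
    labels = np.array([w.label for w in windows], dtype=float)
    if any(w.label is None for w in windows):
        raise ValueError("all training windows need a label")
    if len(np.unique(labels)) < 2:
        raise ValueError("training windows contain a single outcome class")
    X = encode_windows(windows, config.encoding)
    net = LSTMBinaryClassifier(X.shape[2], config.hidden_size, seed=config.seed)
    net.fit(X, labels, epochs=config.epochs, batch_size=config.batch_size,
            lr=config.learning_rate)
    # Refit the logistic readout on the trained recurrent features with
    # a fully converged, weakly regularized solver.  The time-mean input
    # feature carries exact stage-duration fractions, so morphokinetic
    # decision boundaries need near-frame resolution that end-to-end
    # Adam leaves under-sharpened; the refit also calibrates the
    # probabilities the ensemble later thresholds at 0.5.
    from sklearn.linear_model import LogisticRegression

    head = LogisticRegression(C=1e4, max_iter=5000).fit(net.features(X), labels.astype(int))
    return TemporalModel(net=net, config=config, head=head)


def predict_temporal(model: TemporalModel, window: TemporalWindow) -> float:
    """Positive-class probability for one window."""
    return float(model.predict([window])[0])
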