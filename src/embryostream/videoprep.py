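"""Video preparation: 1-cell recognition, pronucleus (PN) presence
estimation, the run-length correction filter, pronuclear-fading (PNF)
localization, and video screening.

Time-lapse videos of IVF- and ICSI-fertilized embryos differ
systematically in cleavage timing, so the pipeline aligns every video on
the PNF frame — the moment the two pronuclei fuse and disappear — before
any downstream modeling.  PNF is found by classifying each frame of the
1-cell stage for PN presence, cleaning the resulting 0/1 sequence with a
correction filter, and taking the last remaining 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

import numpy as np

from .nn import SoftmaxMLP

__all__ = [
    "EmbryoVideo",
    "BinarySequence",
    "PNFEstimate",
    "ScreenDecision",
    "FrameClassifier",
    "train_one_cell_model",
    "train_pn_model",
    "classify_one_cell",
    "detect_pn",
    "correct_sequence",
    "locate_pnf",
    "pnf_is_correct",
    "screen_video",
    "MIN_RETAINED_FRAMES",
    "PNF_WINDOW_BEFORE",
    "PNF_WINDOW_AFTER",
]

#: videos must be strictly longer than this many frames to be retained
MIN_RETAINED_FRAMES = 750
#: the temporal window spans PNF-100 .. PNF+499 (inclusive)
PNF_WINDOW_BEFORE = 100
PNF_WINDOW_AFTER = 499


@dataclass
class EmbryoVideo:
    """An ordered grayscale frame stack captured every ``frame_interval``
    minutes (5 by default, giving ~750-800 frames over three days)."""

    frames: np.ndarray  # (n_frames, H, W) uint8
    method: str = "IVF"  # "IVF" or "ICSI"
    frame_interval: float = 5.0
    video_id: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise ValueError("frames must be a non-empty (n, H, W) stack")
        if self.method not in ("IVF", "ICSI"):
            raise ValueError(f"unknown fertilization method {self.method!r}")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class BinarySequence:
    """Per-frame 0/1 sequence (PN presence or 1-cell indicator)."""

    values: np.ndarray
    semantics: str = "pn_presence"  # or "one_cell"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("sequence must be binary")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PNFEstimate:
    frame: int
    found: bool


@dataclass(frozen=True)
class ScreenDecision:
    retain: bool
    reason: str | None = None  # "too_short" | "pnf_not_found" | "window_out_of_range"


# ---------------------------------------------------------------------------
# frame classifiers
# ---------------------------------------------------------------------------


def preprocess_frames(frames: np.ndarray, downsample: int) -> np.ndarray:
    """Block-mean downsample and scale pixel values to [0, 1], flattened."""
    frames = np.asarray(frames, dtype=np.float32) / 255.0
    if downsample > 1:
        n, h, w = frames.shape
        h2, w2 = h // downsample, w // downsample
        frames = frames[:, : h2 * downsample, : w2 * downsample]
        frames = frames.reshape(n, h2, downsample, w2, downsample).mean(axis=(2, 4))
    return frames.reshape(len(frames), -1)


@dataclass
class FrameClassifier:
    """A compact MLP over downsampled pixels behind the pluggable
    frame-classifier interface (the reference architecture in the field
    is a deep CNN such as DenseNet201; any drop-in exposing
    ``predict``/``predict_proba``/``embed`` works)."""

    mlp: SoftmaxMLP
    downsample: int = 1
    task: str = ""

    def predict(self, frames: np.ndarray) -> np.ndarray:
        return self.mlp.predict(preprocess_frames(frames, self.downsample))

    def predict_proba(self, frames: np.ndarray) -> np.ndarray:
        return self.mlp.predict_proba(preprocess_frames(frames, self.downsample))

    def embed(self, frames: np.ndarray) -> np.ndarray:
        return self.mlp.hidden(preprocess_frames(frames, self.downsample))

    @property
    def embed_dim(self) -> int:
        return self.mlp.hidden_dims[-1]


def _train_binary_frame_model(
    frames: np.ndarray, labels: np.ndarray, task: str, seed: int,
    hidden: int = 64, epochs: int = 25, downsample: int = 1,
) -> FrameClassifier:
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError(f"{task} training data must contain both classes")
    X = preprocess_frames(frames, downsample)
    mlp = SoftmaxMLP(X.shape[1], (hidden,), 2, seed=seed)
    mlp.fit(X, labels, epochs=epochs)
    return FrameClassifier(mlp, downsample=downsample, task=task)


def train_one_cell_model(frames: np.ndarray, one_cell_labels: np.ndarray, seed: int = 0) -> FrameClassifier:
    """Train the binary 1-cell vs multicell frame classifier."""
    return _train_binary_frame_model(frames, one_cell_labels, "one_cell", seed)


def train_pn_model(frames: np.ndarray, pn_labels: np.ndarray, seed: int = 0) -> FrameClassifier:
    """Train the PN presence classifier (on 1-cell-stage frames only)."""
    return _train_binary_frame_model(frames, pn_labels, "pn_presence", seed)


def classify_one_cell(video: EmbryoVideo, model: FrameClassifier) -> BinarySequence:
    """Classify every frame as 1-cell (1) or multicell (0)."""
    return BinarySequence(model.predict(video.frames), semantics="one_cell")


def detect_pn(video: EmbryoVideo, one_cell: BinarySequence, model: FrameClassifier) -> BinarySequence:
    """PN presence per frame; frames outside the 1-cell stage are 0.

    Masking (rather than dropping) non-1-cell frames keeps the sequence
    aligned with the frame index.
    """
    if len(one_cell) != len(video):
        raise ValueError("one_cell sequence length does not match the video")
    out = np.zeros(len(video), dtype=np.int8)
    mask = one_cell.values == 1
    if mask.any():
        out[mask] = model.predict(video.frames[mask])
    return BinarySequence(out, semantics="pn_presence")


# ---------------------------------------------------------------------------
# correction filter
# ---------------------------------------------------------------------------


def _rle(values: list[int]) -> list[list[int]]:
    """Run-length decomposition as [value, length] pairs."""
    return [[v, len(list(grp))] for v, grp in groupby(values)]


def correct_sequence(seq: BinarySequence, k: int = 6, max_passes: int = 50) -> BinarySequence:
    """Suppress noisy segments in a binary sequence.

    A noisy segment is a run whose value differs from its two flanking
    runs of consecutive equal values.  For i = 1..k in order, an interior
    run of length exactly i is flipped when its flank lengths satisfy
    (j_left >= i and j_right >= i+1) or (j_right >= i and j_left >= i+1);
    within a pass corrections apply leftmost-first, each starting from
    the previous correction's result, and the whole k-pass repeats until
    a fixed point.  Runs touching either boundary have only one neighbor
    and are never corrected.
    """
    values = list(int(v) for v in seq.values)
    for _ in range(max_passes):
        before = list(values)
        for i in range(1, k + 1):
            while True:
                runs = _rle(values)
                pos = 0
                flipped = False
                for r in range(len(runs)):
                    val, num = runs[r]
                    if 0 < r < len(runs) - 1 and num == i:
                        j_left, j_right = runs[r - 1][1], runs[r + 1][1]
                        if (j_left >= i and j_right >= i + 1) or (j_right >= i and j_left >= i + 1):
                            values[pos : pos + num] = [1 - val] * num
                            flipped = True
                            break
                    pos += num
                if not flipped:
                    break
        if values == before:
            return BinarySequence(np.array(values, dtype=np.int8), semantics=seq.semantics)
    raise RuntimeError(f"correction filter did not converge within {max_passes} passes")


# ---------------------------------------------------------------------------
# PNF localization and screening
# ---------------------------------------------------------------------------


def locate_pnf(seq: BinarySequence) -> PNFEstimate:
    """PNF frame = index of the last 1 in the corrected PN sequence."""
    ones = np.flatnonzero(seq.values == 1)
    if len(ones) == 0:
        return PNFEstimate(frame=-1, found=False)
    return PNFEstimate(frame=int(ones[-1]), found=True)


def pnf_is_correct(estimate: PNFEstimate, labeled: int, tol: int = 10) -> bool:
    """PN fades gradually, so an estimate within ``tol`` frames (default
    10) of the annotated frame counts as correct."""
    if not estimate.found:
        return False
    return abs(estimate.frame - int(labeled)) <= tol


def screen_video(video: EmbryoVideo, pnf: PNFEstimate) -> ScreenDecision:
    """Retain a video only if it is strictly longer than 750 frames, PNF
    was found, and the full PNF-100..PNF+499 analysis window fits."""
    n = len(video)
    if n <= MIN_RETAINED_FRAMES:
        return ScreenDecision(False, "too_short")
    if not pnf.found:
        return ScreenDecision(False, "pnf_not_found")
    if pnf.frame < PNF_WINDOW_BEFORE or pnf.frame + PNF_WINDOW_AFTER > n - 1:
        return ScreenDecision(False, "window_out_of_range")
    return ScreenDecision(True, None)
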