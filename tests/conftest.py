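"""Shared fixtures.

The expensive artifacts — the default 500-video synthetic study, its
prepared features, the two end-to-end task runs, and the
deterministic-morphokinetics recovery experiment — are session-scoped so
every test that needs them shares one computation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import embryostream as es
from embryostream import ensemble as en
from embryostream import temporal as tp
from embryostream.counting import StageTagSequence
from embryostream.synthetic import stage_of_frames

warnings.filterwarnings("ignore", module="sklearn")
warnings.filterwarnings("ignore", module="lightgbm")
warnings.filterwarnings("ignore", message="X does not have valid feature names")

#: fixed study seed for the shared fixtures
STUDY_SEED = 2026


@pytest.fixture(scope="session")
def study_spec() -> es.GeneratorSpec:
    """The default study conditions: 500 videos, default generator."""
    return es.GeneratorSpec(n_videos=500, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_dataset(study_spec):
    return es.synthetic.generate_dataset(study_spec)


@pytest.fixture(scope="session")
def prepared(study_dataset):
    """Preparation + feature extraction over the 500-video study."""
    return en.prepare_dataset(study_dataset, en.PipelineConfig(), seed=STUDY_SEED)


@pytest.fixture(scope="session")
def blastocyst_run(prepared):
    return en.run_task(prepared, "blastocyst", en.PipelineConfig(), seed=STUDY_SEED)


@pytest.fixture(scope="session")
def usable_run(prepared):
    return en.run_task(prepared, "usable", en.PipelineConfig(), seed=STUDY_SEED)


def ground_truth_windows(dataset, label_fn):
    """PNF-anchored windows from ground-truth stage tags (no rendering),
    labeled by ``label_fn(schedule)``; skips videos whose window does
    not fit."""
    windows = []
    for sched in dataset.schedules:
        if sched.pnf_frame >= 100 and sched.pnf_frame + 499 < sched.n_frames:
            tags = StageTagSequence(np.arange(sched.n_frames), stage_of_frames(sched))
            windows.append(
                tp.extract_temporal_window(tags, sched.pnf_frame, label_fn(sched))
            )
    return windows


@pytest.fixture(scope="session")
def temporal_recovery():
    """Temporal stream trained on n=500 embryos whose label is a
    deterministic threshold on the 2->3-cell interval, with perfect
    stage tags; returns (model, validation windows, validation labels)."""
    ds = es.synthetic.generate_dataset(es.GeneratorSpec(n_videos=500, seed=STUDY_SEED + 1))
    wins = ground_truth_windows(ds, lambda s: int(s.intervals[1] <= 120))
    n_train = len(wins) - int(round(0.2 * len(wins)))
    train, val = wins[:n_train], wins[n_train:]
    model = tp.train_temporal(train, tp.TemporalModelConfig(seed=STUDY_SEED))
    return model, val, np.array([w.label for w in val])


@pytest.fixture(scope="session")
def small_models():
    """Quickly trained preparation models (20 annotation videos) for the
    frame-level unit tests."""
    ds = es.synthetic.generate_dataset(es.GeneratorSpec(n_videos=20, seed=9))
    return en.train_preparation_models(ds, en.PipelineConfig(), seed=9)


@pytest.fixture(scope="session")
def holdout_dataset():
    """A small held-out synthetic set, disjoint seed from all training."""
    return es.synthetic.generate_dataset(es.GeneratorSpec(n_videos=6, seed=909))
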