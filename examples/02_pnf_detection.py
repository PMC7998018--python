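"""Locate pronuclear fading (PNF) in a synthetic video.

Pipeline: classify each frame 1-cell vs multicell, estimate PN presence
inside the 1-cell stage, clean the binary sequence with the run-length
correction filter, and take the last remaining 1 as the PNF frame.
"""

import numpy as np

from embryostream import GeneratorSpec, generate_dataset
from embryostream.ensemble import PipelineConfig, train_preparation_models
from embryostream.videoprep import (
    classify_one_cell, correct_sequence, detect_pn, locate_pnf, screen_video,
)

train_ds = generate_dataset(GeneratorSpec(n_videos=20, seed=0))
one_cell_model, pn_model, _ = train_preparation_models(train_ds, PipelineConfig(), seed=0)

test_ds = generate_dataset(GeneratorSpec(n_videos=3, seed=99))
for i in range(test_ds.n):
    video, _ = test_ds.video(i)
    raw = detect_pn(video, classify_one_cell(video, one_cell_model), pn_model)
    cleaned = correct_sequence(raw)
    est = locate_pnf(cleaned)
    decision = screen_video(video, est)
    truth = test_ds.schedules[i].pnf_frame
    flips = int(np.sum(raw.values != cleaned.values))
    print(f"{video.video_id}: PNF estimated {est.frame} vs true {truth} "
          f"(|err|={abs(est.frame - truth)}, filter flipped {flips} frames, "
          f"screening: {'retain' if decision.retain else decision.reason})")
# An estimate within 10 frames (50 minutes of culture time) counts as
# correct; screening additionally demands >750 frames and room for the
# PNF-100..PNF+499 analysis window.
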