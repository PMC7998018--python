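"""Train the temporal and spatial streams separately on ground truth.

The temporal stream reads the 600-frame PNF-anchored stage-tag window
(morphokinetics); the spatial stream reads embeddings of the 35
checkpoint frames (morphology).  Here both are trained on small
ground-truth data to show the interfaces without the full pipeline.
"""

import numpy as np

from embryostream import GeneratorSpec, generate_dataset
from embryostream.counting import StageTagSequence
from embryostream.ensemble import roc_auc
from embryostream.spatial import (
    SpatialModelConfig, checkpoint_indices, embed_frames,
    extract_checkpoint_frames, train_spatial,
)
from embryostream.synthetic import stage_of_frames
from embryostream.temporal import TemporalModelConfig, extract_temporal_window, train_temporal
from embryostream.ensemble import PipelineConfig, train_preparation_models

ds = generate_dataset(GeneratorSpec(n_videos=120, seed=5))
ann = generate_dataset(GeneratorSpec(n_videos=15, seed=6))
_, _, backbone = train_preparation_models(ann, PipelineConfig(frames_per_annotation_video=25), seed=6)

windows, mats, labels = [], [], []
for i, sched in enumerate(ds.schedules):
    if not (sched.pnf_frame >= 100 and sched.pnf_frame + 499 < sched.n_frames):
        continue
    tags = StageTagSequence(np.arange(sched.n_frames), stage_of_frames(sched))
    windows.append(extract_temporal_window(tags, sched.pnf_frame,
                                           int(ds.labels.blastocyst.iloc[i])))
    video, _ = ds.video(i)
    mats.append(embed_frames(extract_checkpoint_frames(video, sched.pnf_frame), backbone))
    labels.append(int(ds.labels.blastocyst.iloc[i]))

labels = np.array(labels)
n_val = len(labels) // 5
t_model = train_temporal(windows[:-n_val], TemporalModelConfig(epochs=40, seed=1))
s_model = train_spatial(mats[:-n_val], labels[:-n_val], SpatialModelConfig(seed=1))

pt = t_model.predict(windows[-n_val:])
ps = s_model.predict_proba(mats[-n_val:])
print(f"checkpoint indices for PNF=235: {checkpoint_indices(235)[:7]} ... (35 total)")
print(f"temporal stream validation AUC: {roc_auc(pt, labels[-n_val:])[1]:.3f}")
print(f"spatial  stream validation AUC: {roc_auc(ps, labels[-n_val:])[1]:.3f}")
# Blastocyst formation is driven by cleavage timing, so the temporal
# stream should dominate; the spatial stream still sees timing through
# the cell count visible at the day-2/day-3 checkpoints.
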