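"""Generate a small synthetic time-lapse dataset and inspect it.

Each synthetic embryo gets a cleavage schedule (pronuclear appearance
and fading, four division times, a morphology score), binary outcomes
coupled to those quantities, and a rendered grayscale frame stack.
"""

import numpy as np

from embryostream import GeneratorSpec, generate_dataset

spec = GeneratorSpec(n_videos=8, seed=42)
ds = generate_dataset(spec)

print(ds.labels[["video_id", "method", "n_frames", "pnf_frame",
                 "morphology_score", "blastocyst", "usable"]].to_string(index=False))

video, truth = ds.video(0)
shares = np.bincount(truth.stages, minlength=6)[1:] / len(video)
print(f"\nvideo 0: {video.frames.shape} uint8 frames, method {video.method}")
print("stage frame shares (1..5+):", np.round(shares, 3))
# The 3-cell stage should hold the smallest share: embryos pass through
# it quickly, which is exactly the class imbalance the counting model
# has to cope with.
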