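"""Synthetic time-lapse embryo videos with ground truth.

Clinical time-lapse videos of human embryos are not publicly shareable,
so this module generates stacks with the statistical structure the
pipeline assumes: a 1-cell stage in which two pronuclei (PN) appear and
later fade (PNF), cleavage events producing 2-, 3-, 4- and >=5-cell
stages with realistic stage-duration imbalance (the 3-cell stage is by
far the shortest), frame-level degradation emulating indecipherable
frames, and binary outcomes (blastocyst formation; usable-blastocyst
quality) statistically coupled to both cleavage timings and a rendered
morphology score.  IVF- and ICSI-fertilized videos differ in their PNF
distribution (truncated normals with means 235 and 271 frames,
truncation 150-300 and 200-350), which is exactly the misalignment the
preparation stage must undo.

Everything is deterministic given the generator spec and its seed; a
video can be re-rendered lazily at any time, byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.special import ndtri
from scipy.stats import truncnorm

from .videoprep import EmbryoVideo

__all__ = [
    "GeneratorSpec",
    "CleavageSchedule",
    "GroundTruth",
    "sample_schedule",
    "assign_outcome",
    "render_video",
    "stage_of_frames",
    "SyntheticDataset",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
]

_MIN_IMAGE_SIZE = 32
_OUTCOME_RULES = ("threshold",)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for a synthetic dataset.

    Defaults reproduce the conditions the pipeline was designed for:
    ~750-800 frames per video at 5-minute intervals, PNF means of 235
    (IVF) and 271 (ICSI) frames, and cleavage-interval means chosen so
    the frame shares of the 1/2/3/4/>=5-cell stages fall near
    42/16/6/18/18% with the 3-cell stage rarest.
    """

    n_videos: int = 500
    frame_count_range: tuple[int, int] = (750, 800)
    fertilization_mix: float = 0.5  # fraction ICSI
    pnf_mean_ivf: float = 235.0
    pnf_mean_icsi: float = 271.0
    pnf_sd: float = 30.0
    pnf_range_ivf: tuple[float, float] = (150.0, 300.0)
    pnf_range_icsi: tuple[float, float] = (200.0, 350.0)
    pn_appear_mean: float = 40.0
    pn_appear_sd: float = 10.0
    #: mean frames between PNF->2c, 2c->3c, 3c->4c, 4c->5c transitions
    cleavage_interval_means: tuple[float, float, float, float] = (90.0, 120.0, 45.0, 140.0)
    cleavage_interval_sds: tuple[float, float, float, float] = (20.0, 30.0, 12.0, 30.0)
    stage_noise_rate: float = 0.02  # probability a frame renders degraded
    label_noise: float = 0.05
    blastocyst_rate: float = 0.55  # target prevalence of the positive class
    usable_rate: float = 0.35
    outcome_rule: str = "threshold"
    image_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.n_videos < 1:
            raise ValueError("n_videos must be >= 1")
        lo, hi = self.frame_count_range
        if not (1 <= lo <= hi):
            raise ValueError("frame_count_range must satisfy 1 <= lo <= hi")
        for name in ("fertilization_mix", "stage_noise_rate", "label_noise",
                     "blastocyst_rate", "usable_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pnf_mean_ivf <= 0 or self.pnf_mean_icsi <= 0 or self.pnf_sd < 0:
            raise ValueError("PNF distribution parameters must be positive (sd >= 0)")
        if any(m <= 0 for m in self.cleavage_interval_means):
            raise ValueError("cleavage interval means must be positive")
        if any(s < 0 for s in self.cleavage_interval_sds):
            raise ValueError("cleavage interval sds must be non-negative")
        if self.usable_rate > self.blastocyst_rate:
            raise ValueError("usable_rate cannot exceed blastocyst_rate "
                             "(usable blastocysts are a subset of blastocysts)")
        if self.outcome_rule not in _OUTCOME_RULES:
            raise ValueError(f"unknown outcome_rule {self.outcome_rule!r}")
        if self.image_size < _MIN_IMAGE_SIZE:
            raise ValueError(f"image_size must be >= {_MIN_IMAGE_SIZE} to place cell discs")


@dataclass(frozen=True)
class CleavageSchedule:
    """Per-embryo morphokinetic ground truth."""

    method: str  # "IVF" or "ICSI"
    n_frames: int
    pn_appear_frame: int
    pnf_frame: int
    division_frames: tuple[int, int, int, int]  # first frame of 2,3,4,5+ cells
    morphology_score: float  # in [0, 1]

    def __post_init__(self):
        d = self.division_frames
        if not all(d[i] < d[i + 1] for i in range(len(d) - 1)):
            raise ValueError("division_frames must be strictly increasing")
        if self.pnf_frame > d[0]:
            raise ValueError("PNF must not occur after the first division")
        if not 0.0 <= self.morphology_score <= 1.0:
            raise ValueError("morphology_score must be in [0, 1]")

    @property
    def intervals(self) -> tuple[int, ...]:
        prev = self.pnf_frame
        out = []
        for f in self.division_frames:
            out.append(f - prev)
            prev = f
        return tuple(out)


@dataclass
class GroundTruth:
    stages: np.ndarray  # per-frame cell stage in {1,2,3,4,5}
    pn: np.ndarray  # per-frame PN presence 0/1
    blastocyst_label: int
    usable_label: int


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_schedule(
    spec: GeneratorSpec, rng: np.random.Generator, method: str | None = None
) -> CleavageSchedule:
    """Draw one embryo's cleavage schedule.

    PNF comes from the method-specific truncated normal; division frames
    are PNF plus cumulative positive cleavage intervals; the morphology
    score is uniform on [0, 1].
    """
    if method is None:
        method = "ICSI" if rng.random() < spec.fertilization_mix else "IVF"
    for _ in range(100):
        if method == "ICSI":
            pnf = _trunc_normal(rng, spec.pnf_mean_icsi, spec.pnf_sd, *spec.pnf_range_icsi)
        else:
            pnf = _trunc_normal(rng, spec.pnf_mean_ivf, spec.pnf_sd, *spec.pnf_range_ivf)
        pnf = int(round(pnf))
        appear = int(round(rng.normal(spec.pn_appear_mean, spec.pn_appear_sd)))
        appear = int(np.clip(appear, 0, pnf - 1))
        intervals = [
            max(1, int(round(rng.normal(m, s))))
            for m, s in zip(spec.cleavage_interval_means, spec.cleavage_interval_sds)
        ]
        divisions = tuple(int(pnf + c) for c in np.cumsum(intervals))
        n_frames = int(rng.integers(spec.frame_count_range[0], spec.frame_count_range[1] + 1))
        morph = float(rng.uniform(0.0, 1.0))
        if 0 <= appear < pnf <= divisions[0]:
            return CleavageSchedule(method, n_frames, appear, pnf, divisions, morph)
    raise RuntimeError("could not sample a valid cleavage schedule in 100 attempts")


def assign_outcome(
    schedule: CleavageSchedule, spec: GeneratorSpec, rng: np.random.Generator
) -> tuple[int, int]:
    """Couple labels to morphokinetics and morphology.

    The default "threshold" rule standardizes the first three cleavage
    intervals against the generator means/sds and calls the embryo a
    blastocyst when the summed delay score stays below the quantile that
    yields the target prevalence; usable additionally requires the
    morphology score to clear the quantile implied by the target usable
    rate.  ``label_noise`` flips each component independently; the
    usable label always remains a subset of the blastocyst label.
    """
    if spec.outcome_rule != "threshold":
        raise ValueError(f"unknown outcome_rule {spec.outcome_rule!r}")
    z = 0.0
    m = 0
    for iv, mean, sd in zip(
        schedule.intervals[:3], spec.cleavage_interval_means[:3], spec.cleavage_interval_sds[:3]
    ):
        if sd > 0:
            z += (iv - mean) / sd
            m += 1
    thr = np.sqrt(max(m, 1)) * ndtri(spec.blastocyst_rate)
    blast = int(z <= thr)
    morph_thr = 1.0 - (spec.usable_rate / spec.blastocyst_rate if spec.blastocyst_rate > 0 else 1.0)
    usable_core = int(schedule.morphology_score >= morph_thr)
    if spec.label_noise > 0:
        if rng.random() < spec.label_noise:
            blast = 1 - blast
        if rng.random() < spec.label_noise:
            usable_core = 1 - usable_core
    return blast, int(blast and usable_core)


def stage_of_frames(schedule: CleavageSchedule, n_frames: int | None = None) -> np.ndarray:
    """Per-frame cell stage in {1..5}; monotone non-decreasing."""
    n = schedule.n_frames if n_frames is None else n_frames
    stages = 1 + np.searchsorted(np.asarray(schedule.division_frames), np.arange(n), side="right")
    return np.minimum(stages, 5).astype(np.int8)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

# unit cell-centre offsets (fractions of the well radius) per stage
_LAYOUT_OFFSETS = {
    1: [(0.0, 0.0)],
    2: [(0.0, -0.48), (0.0, 0.48)],
    3: [(-0.5, 0.0), (0.38, -0.38), (0.38, 0.38)],
    4: [(-0.4, -0.4), (-0.4, 0.4), (0.4, -0.4), (0.4, 0.4)],
    5: [(0.0, 0.0), (-0.42, -0.42), (-0.42, 0.42), (0.42, -0.42), (0.42, 0.42)],
}
_BACKGROUND, _WELL, _NOISE_SD = 15.0, 50.0, 6.0


def _rotate(offsets, angle):
    c, s = np.cos(angle), np.sin(angle)
    return [(c * dy - s * dx, s * dy + c * dx) for dy, dx in offsets]


def _base_image(size: int, stage: int, pn: bool, morph: float, angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2.0
    well_r = 0.46 * size
    img = np.full((size, size), _BACKGROUND)
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= well_r**2] = _WELL
    cell_r = 0.62 * well_r * stage ** (-1.0 / 3.0)
    if cell_r < 2.0:
        raise ValueError("image_size too small to place cell discs")
    cyto = 90.0 + 50.0 * morph
    centers = [
        (cy + dy * well_r, cx + dx * well_r) for dy, dx in _rotate(_LAYOUT_OFFSETS[stage], angle)
    ]
    for ccy, ccx in centers:
        d2 = (yy - ccy) ** 2 + (xx - ccx) ** 2
        mask = d2 <= cell_r**2
        # mild radial shading gives the discs a cell-like falloff
        img[mask] = cyto * (1.0 - 0.25 * d2[mask] / cell_r**2)
    if pn:
        pn_r = max(2.0, 0.07 * size)
        off = 0.35 * cell_r
        for sign in (-1.0, 1.0):
            d2 = (yy - cy) ** 2 + (xx - (cx + sign * off)) ** 2
            img[d2 <= pn_r**2] = min(cyto + 70.0, 250.0)
    return img


def render_video(
    schedule: CleavageSchedule, spec: GeneratorSpec, rng: np.random.Generator, video_id: str = ""
) -> tuple[EmbryoVideo, GroundTruth]:
    """Render a frame stack plus per-frame ground truth.

    Each frame shows k disc-shaped cells (k = stage) inside a circular
    well; two small bright PN discs appear inside the single cell during
    [pn_appear_frame, pnf_frame].  Cytoplasm brightness encodes the
    morphology score.  Additive Gaussian noise is applied everywhere and
    a fraction ``stage_noise_rate`` of frames is degraded (blur, heavy
    noise and an occluding blob) without changing the ground truth.
    """
    n, size = schedule.n_frames, spec.image_size
    stages = stage_of_frames(schedule)
    pn = np.zeros(n, dtype=np.int8)
    pn[schedule.pn_appear_frame : schedule.pnf_frame + 1] = 1
    pn[stages != 1] = 0  # PN only ever exists in the 1-cell stage

    angles = {s: float(rng.uniform(0, 2 * np.pi)) for s in range(1, 6)}
    bases: dict[tuple[int, int], np.ndarray] = {}
    frames = np.empty((n, size, size), dtype=np.uint8)
    degraded = rng.random(n) < spec.stage_noise_rate
    for t in range(n):
        key = (int(stages[t]), int(pn[t]))
        if key not in bases:
            bases[key] = _base_image(size, key[0], bool(key[1]),
                                     schedule.morphology_score, angles[key[0]])
        img = bases[key] + rng.normal(0.0, _NOISE_SD, size=(size, size))
        if degraded[t]:
            img = ndimage.gaussian_filter(img, 3.0)
            img = img + rng.normal(0.0, 40.0, size=(size, size))
            oy, ox = rng.uniform(0.2 * size, 0.8 * size, size=2)
            yy, xx = np.mgrid[0:size, 0:size]
            img[(yy - oy) ** 2 + (xx - ox) ** 2 <= (0.3 * size) ** 2] = _BACKGROUND
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)
    video = EmbryoVideo(frames, method=schedule.method, video_id=video_id)
    truth = GroundTruth(stages=stages, pn=pn, blastocyst_label=-1, usable_label=-1)
    return video, truth


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------


def _video_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index, stream]))


@dataclass
class SyntheticDataset:
    """Lazily rendered dataset: schedules and labels are materialized,
    frame stacks are re-rendered deterministically on demand."""

    spec: GeneratorSpec
    schedules: list[CleavageSchedule]
    labels: pd.DataFrame  # video_id, method, n_frames, pnf, labels, ...

    @property
    def n(self) -> int:
        return len(self.schedules)

    def video(self, i: int) -> tuple[EmbryoVideo, GroundTruth]:
        sched = self.schedules[i]
        video, truth = render_video(
            sched, self.spec, _video_rng(self.spec.seed, i, 2), video_id=self.labels.video_id.iloc[i]
        )
        truth.blastocyst_label = int(self.labels.blastocyst.iloc[i])
        truth.usable_label = int(self.labels.usable.iloc[i])
        return video, truth


def _labels_row(video_id: str, sched: CleavageSchedule, blast: int, usable: int) -> dict:
    d = sched.division_frames
    return dict(
        video_id=video_id, method=sched.method, n_frames=sched.n_frames,
        pn_appear_frame=sched.pn_appear_frame, pnf_frame=sched.pnf_frame,
        div2=d[0], div3=d[1], div4=d[2], div5=d[3],
        morphology_score=round(sched.morphology_score, 6),
        blastocyst=blast, usable=usable,
    )


def generate_dataset(spec: GeneratorSpec) -> SyntheticDataset:
    schedules, rows = [], []
    for i in range(spec.n_videos):
        sched = sample_schedule(spec, _video_rng(spec.seed, i, 0))
        blast, usable = assign_outcome(sched, spec, _video_rng(spec.seed, i, 1))
        schedules.append(sched)
        rows.append(_labels_row(f"emb{i:05d}", sched, blast, usable))
    return SyntheticDataset(spec=spec, schedules=schedules, labels=pd.DataFrame(rows))


def write_dataset(spec: GeneratorSpec, out_dir) -> pd.DataFrame:
    """Write frame stacks (multi-page TIFF), per-frame annotation CSVs
    and a manifest CSV; returns the manifest."""
    import dataclasses
    import json

    out = Path(out_dir)
    (out / "videos").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    (out / "generator_spec.json").write_text(json.dumps(dataclasses.asdict(spec), indent=2))
    ds = generate_dataset(spec)
    rows = []
    for i in range(ds.n):
        vid = ds.labels.video_id.iloc[i]
        video, truth = ds.video(i)
        frames_path = f"videos/{vid}.tif"
        ann_path = f"annotations/{vid}.csv"
        tifffile.imwrite(out / frames_path, video.frames)
        pd.DataFrame(
            dict(frame=np.arange(len(video)), stage=truth.stages, pn=truth.pn)
        ).to_csv(out / ann_path, index=False)
        row = dict(ds.labels.iloc[i])
        row.update(frames_path=frames_path, annotations_path=ann_path)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


@dataclass
class DiskDataset:
    """Dataset read back from :func:`write_dataset` output."""

    root: Path
    labels: pd.DataFrame
    schedules: list[CleavageSchedule]
    spec: GeneratorSpec | None = None

    @property
    def n(self) -> int:
        return len(self.labels)

    def video(self, i: int) -> tuple[EmbryoVideo, GroundTruth]:
        row = self.labels.iloc[i]
        frames = tifffile.imread(self.root / row.frames_path)
        ann = pd.read_csv(self.root / row.annotations_path)
        video = EmbryoVideo(frames, method=row.method, video_id=row.video_id)
        truth = GroundTruth(
            stages=ann.stage.to_numpy(np.int8), pn=ann.pn.to_numpy(np.int8),
            blastocyst_label=int(row.blastocyst), usable_label=int(row.usable),
        )
        return video, truth


def load_dataset(root) -> DiskDataset:
    import json

    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    spec = None
    spec_path = root / "generator_spec.json"
    if spec_path.exists():
        params = json.loads(spec_path.read_text())
        for key, val in params.items():
            if isinstance(val, list):
                params[key] = tuple(val)
        spec = GeneratorSpec(**params)
    schedules = [
        CleavageSchedule(
            method=r.method, n_frames=int(r.n_frames), pn_appear_frame=int(r.pn_appear_frame),
            pnf_frame=int(r.pnf_frame),
            division_frames=(int(r.div2), int(r.div3), int(r.div4), int(r.div5)),
            morphology_score=float(r.morphology_score),
        )
        for r in manifest.itertuples()
    ]
    return DiskDataset(root=root, labels=manifest, schedules=schedules, spec=spec)
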