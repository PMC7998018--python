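"""Generator: schedule sampling, outcome coupling, rendering and I/O."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import embryostream as es
from embryostream.synthetic import (
    CleavageSchedule,
    assign_outcome,
    generate_dataset,
    load_dataset,
    render_video,
    sample_schedule,
    stage_of_frames,
    write_dataset,
)

BASE = es.GeneratorSpec(n_videos=4, seed=0)


def _schedule(intervals, morph=1.0, pnf=235, method="IVF", n_frames=800):
    divisions = tuple(int(pnf + c) for c in np.cumsum(intervals))
    return CleavageSchedule(method, n_frames, 40, pnf, divisions, morph)


class TestSampleSchedule:
    @pytest.mark.parametrize("method,expected", [("IVF", 235), ("ICSI", 271)])
    def test_zero_spread_pins_pnf_at_method_mean(self, method, expected):
        spec = replace(BASE, pnf_sd=0.0)
        sched = sample_schedule(spec, np.random.default_rng(0), method=method)
        assert sched.pnf_frame == expected

    def test_same_seed_gives_identical_schedules(self):
        a = sample_schedule(BASE, np.random.default_rng(42))
        b = sample_schedule(BASE, np.random.default_rng(42))
        assert a == b

    def test_pnf_respects_truncation_range(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            sched = sample_schedule(BASE, rng, method="IVF")
            assert 150 <= sched.pnf_frame <= 300
            assert sched.pnf_frame <= sched.division_frames[0]
            assert all(np.diff(sched.division_frames) > 0)


class TestAssignOutcome:
    def test_on_time_cleaver_with_top_morphology_is_usable_blastocyst(self):
        spec = replace(BASE, label_noise=0.0)
        sched = _schedule(spec.cleavage_interval_means, morph=1.0)
        assert assign_outcome(sched, spec, np.random.default_rng(0)) == (1, 1)

    def test_severely_delayed_first_interval_fails(self):
        spec = replace(BASE, label_noise=0.0)
        means = spec.cleavage_interval_means
        sched = _schedule((3 * means[0], *means[1:]), morph=1.0)
        assert assign_outcome(sched, spec, np.random.default_rng(0)) == (0, 0)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="outcome_rule"):
            es.GeneratorSpec(n_videos=1, outcome_rule="magic")

    def test_usable_implies_blastocyst_over_1000_embryos(self):
        ds = generate_dataset(es.GeneratorSpec(n_videos=1000, seed=3))
        bad = (ds.labels.usable == 1) & (ds.labels.blastocyst == 0)
        assert int(bad.sum()) == 0

    def test_blastocyst_prevalence_near_configured_target(self):
        ds = generate_dataset(es.GeneratorSpec(n_videos=1000, seed=3))
        assert abs(ds.labels.blastocyst.mean() - 0.55) <= 0.05

    def test_three_cell_stage_has_smallest_frame_share(self):
        ds = generate_dataset(es.GeneratorSpec(n_videos=1000, seed=3))
        counts = np.zeros(5)
        for sched in ds.schedules:
            counts += np.bincount(stage_of_frames(sched) - 1, minlength=5)
        shares = counts / counts.sum()
        assert np.argmin(shares) == 2  # 3-cell
        # qualitative match to the observed clinical distribution:
        # 1-cell dominates, 3-cell is rare
        assert shares[0] > 0.3 and shares[2] < 0.1


class TestRendering:
    def test_frame_count_and_pn_ground_truth(self):
        spec = replace(BASE, stage_noise_rate=0.0)
        sched = sample_schedule(spec, np.random.default_rng(5), method="IVF")
        video, truth = render_video(sched, spec, np.random.default_rng(5))
        assert len(video) == sched.n_frames
        assert truth.pn[: sched.pn_appear_frame].sum() == 0
        assert truth.pn[sched.pn_appear_frame] == 1
        assert truth.pn[sched.pnf_frame] == 1
        assert truth.pn[sched.pnf_frame + 1 :].sum() == 0
        assert (np.diff(truth.stages) >= 0).all()

    def test_pn_discs_brighter_than_surrounding_cytoplasm(self):
        """On clean frames the two PN discs must be measurably brighter
        than the cytoplasm around them, for 100/100 sampled frames."""
        spec = replace(BASE, stage_noise_rate=0.0)
        size = spec.image_size
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2.0
        cell_r = 0.62 * 0.46 * size
        pn_r = max(2.0, 0.07 * size)
        pn_mask = np.zeros((size, size), bool)
        for sign in (-1, 1):
            pn_mask |= (yy - c) ** 2 + (xx - (c + sign * 0.35 * cell_r)) ** 2 <= pn_r**2
        cyto_mask = ((yy - c) ** 2 + (xx - c) ** 2 <= (0.8 * cell_r) ** 2) & ~pn_mask

        checked = 0
        rng = np.random.default_rng(8)
        for i in range(20):
            sched = sample_schedule(spec, np.random.default_rng(100 + i))
            video, truth = render_video(sched, spec, np.random.default_rng(200 + i))
            frames = np.flatnonzero(truth.pn == 1)
            for f in rng.choice(frames, size=5, replace=False):
                img = video.frames[f].astype(float)
                assert img[pn_mask].mean() > img[cyto_mask].mean()
                checked += 1
        assert checked == 100

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="image_size"):
            es.GeneratorSpec(n_videos=1, image_size=8)

    def test_rerendering_is_byte_identical(self):
        ds = generate_dataset(es.GeneratorSpec(n_videos=2, seed=6))
        a, _ = ds.video(1)
        b, _ = ds.video(1)
        np.testing.assert_array_equal(a.frames, b.frames)


class TestDatasetIO:
    SMALL = es.GeneratorSpec(n_videos=10, frame_count_range=(40, 60),
                             image_size=32, seed=12)

    def test_manifest_rows_match_video_count(self, tmp_path):
        manifest = write_dataset(self.SMALL, tmp_path)
        assert len(manifest) == 10

    def test_roundtrip_reproduces_labels_and_frames(self, tmp_path):
        manifest = write_dataset(self.SMALL, tmp_path)
        disk = load_dataset(tmp_path)
        mem = generate_dataset(self.SMALL)
        pd.testing.assert_frame_equal(
            disk.labels[mem.labels.columns], mem.labels, check_dtype=False
        )
        for i in (0, 7):
            dv, dt = disk.video(i)
            mv, mt = mem.video(i)
            np.testing.assert_array_equal(dv.frames, mv.frames)
            np.testing.assert_array_equal(dt.stages, mt.stages)
            np.testing.assert_array_equal(dt.pn, mt.pn)

    def test_same_seed_twice_gives_identical_manifests(self, tmp_path):
        m1 = write_dataset(self.SMALL, tmp_path / "a")
        m2 = write_dataset(self.SMALL, tmp_path / "b")
        pd.testing.assert_frame_equal(m1, m2)
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == \
               (tmp_path / "b" / "manifest.csv").read_bytes()
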