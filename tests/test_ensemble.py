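"""Weighted ensemble, metric suite, weight search and pipeline wiring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import embryostream as es
from embryostream import ensemble as en
from embryostream.ensemble import (
    EnsembleWeight,
    classify,
    compute_metrics,
    ensemble_score,
    roc_auc,
    search_weight,
    split_indices,
)

from _oracles import pair_counting_auc


class TestEnsembleScore:
    def test_weighted_average_at_published_style_weight(self):
        assert ensemble_score(0.9, 0.5, EnsembleWeight(0.66)) == pytest.approx(0.764, abs=1e-12)

    def test_degenerate_weights_return_a_single_stream(self):
        assert ensemble_score(0.7, 0.2, EnsembleWeight(1.0)) == 0.7
        assert ensemble_score(0.7, 0.2, EnsembleWeight(0.0)) == 0.2

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0, 1), st.integers(0, 100))
    def test_convexity_identity(self, x, wi):
        assert ensemble_score(x, x, EnsembleWeight(wi / 100)) == pytest.approx(x)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            ensemble_score(1.2, 0.5, EnsembleWeight(0.5))
        with pytest.raises(ValueError):
            EnsembleWeight(0.555)  # off the 0.01 grid


class TestClassify:
    @pytest.mark.parametrize("score,call", [(0.5, 1), (0.49, 0), (1.0, 1), (0.0, 0)])
    def test_threshold_boundary(self, score, call):
        assert classify(score) == call


class TestWeightSearch:
    def test_matches_brute_force_on_small_fixture(self):
        rng = np.random.default_rng(0)
        pt, ps = rng.random(6), rng.random(6)
        y = np.array([1, 0, 1, 1, 0, 0])
        best_w, best_acc = search_weight(pt, ps, y)
        # independent brute force over the same grid
        expect_w, expect_acc = None, -1.0
        for j in range(101):
            w = j / 100
            acc = float(np.mean(((w * pt + (1 - w) * ps) >= 0.5).astype(int) == y))
            if acc > expect_acc:
                expect_w, expect_acc = w, acc
        assert best_w.w_temporal == pytest.approx(expect_w)
        assert best_acc == pytest.approx(expect_acc)

    def test_perfect_temporal_stream_dominates(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        pt = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        ps = np.array([0.6, 0.4, 0.7, 0.3, 0.6, 0.4])
        w, acc = search_weight(pt, ps, y)
        assert acc == 1.0

    def test_identical_streams_tie_break_to_smallest_weight(self):
        scores = np.array([0.2, 0.8, 0.6, 0.4])
        y = np.array([0, 1, 1, 0])
        w, acc = search_weight(scores, scores, y)
        assert w.w_temporal == 0.0 and acc == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            search_weight(np.array([]), np.array([]), np.array([]))


class TestMetrics:
    def test_implantation_worked_example(self):
        """209 transferred embryos: 160 called usable (81 implanted, 79
        failed), 49 called unusable (21 implanted, 28 failed)."""
        calls = np.array([1] * 160 + [0] * 49)
        labels = np.array([1] * 81 + [0] * 79 + [1] * 21 + [0] * 28)
        m = compute_metrics(calls, labels)
        assert (m.tp, m.fp, m.fn, m.tn) == (81, 79, 21, 28)
        assert m.ppv == pytest.approx(81 / 160)
        rate_unusable = m.fn / (m.fn + m.tn)
        assert round(100 * m.ppv, 1) == 50.6
        assert round(100 * rate_unusable, 1) == 42.9

    def test_perfect_calls_score_one_everywhere(self):
        y = np.array([0, 1, 1, 0, 1])
        m = compute_metrics(y, y)
        assert m.sensitivity == m.specificity == m.accuracy == 1.0

    def test_zero_denominators_are_undefined_not_zero(self):
        m = compute_metrics(np.ones(4, dtype=int), np.array([1, 0, 1, 0]))
        assert m.npv is None  # no negative calls
        assert m.specificity == 0.0  # defined: real negatives exist

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([1, 0]), np.array([1]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_identities(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 2, 30)
        labels = rng.integers(0, 2, 30)
        m = compute_metrics(calls, labels)
        assert m.tp + m.tn + m.fp + m.fn == 30
        if m.sensitivity is not None:
            assert m.sensitivity * (m.tp + m.fn) == pytest.approx(m.tp)
        swapped = compute_metrics(1 - calls, 1 - labels)
        assert swapped.accuracy == pytest.approx(m.accuracy)


class TestRocAuc:
    def test_perfect_separation_and_all_ties(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y)[1] == 1.0
        assert roc_auc(np.full(4, 0.5), y)[1] == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 5, 20) / 4.0  # coarse grid forces ties
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_roc_points_plot_sensitivity_against_fpr(self):
        points, _ = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert {"threshold", "fpr", "sensitivity"} <= set(points.columns)
        assert points.sensitivity.iloc[-1] == 1.0 and points.fpr.iloc[-1] == 1.0


class TestPipeline:
    def test_eighty_twenty_split_arithmetic(self):
        train, val = split_indices(500, 0.2, seed=0)
        assert len(train) == 400 and len(val) == 100
        assert len(np.intersect1d(train, val)) == 0
        assert len(np.union1d(train, val)) == 500

    def test_unknown_task_rejected(self, prepared):
        with pytest.raises(ValueError, match="task"):
            en.run_task(prepared, "pregnancy")

    def test_usable_task_end_to_end_auc(self, usable_run):
        """Usable-blastocyst prediction needs both streams (kinetics for
        blastocyst formation, rendered morphology for quality); the
        ensemble should rank validation embryos well."""
        assert usable_run.metrics.auc >= 0.80

    def test_screening_feasibility_guarantee(self, prepared):
        """Every retained video must support the 600-frame window and
        all 35 checkpoint indices."""
        from embryostream.spatial import checkpoint_indices

        for win, pnf in zip(prepared.windows, prepared.pnf_estimates):
            assert len(win.tags) == 600
            idx = checkpoint_indices(pnf)
            assert idx[0] >= pnf - 100 and idx[-1] <= pnf + 499

    def test_small_pipeline_run_is_seed_deterministic(self, tmp_path):
        import pandas as pd

        spec = es.GeneratorSpec(n_videos=40, seed=31)
        ds = es.synthetic.generate_dataset(spec)
        # annotation set must stay large enough for a usable PN model:
        # a sloppy PN model pushes every PNF estimate so late that the
        # 600-frame window no longer fits and screening empties the set
        cfg = en.PipelineConfig(
            counting=es.StageClassifierConfig(hidden_dims=(64,), epochs=8),
            temporal=en.tp.TemporalModelConfig(hidden_size=8, epochs=6),
            spatial=en.sp.SpatialModelConfig(n_estimators=10),
            n_annotation_videos=15, frames_per_annotation_video=30,
        )
        a = en.run_pipeline(ds, "blastocyst", cfg, seed=4)
        b = en.run_pipeline(ds, "blastocyst", cfg, seed=4)
        pd.testing.assert_frame_equal(a.records, b.records)
        assert a.weight == b.weight and a.metrics.to_dict() == b.metrics.to_dict()
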