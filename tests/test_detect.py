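"""Top-N detection protocol and TPF/FPF evaluation on constructed cases."""

import numpy as np
import pytest

from fastnccc.detect import (Detection, detections_to_frame,
                             detections_to_label, top_n_detections, tpf_fpf,
                             tpf_fpf_curve)
from fastnccc.scan import NCCCResult, TemplateConfig, nccc_maximized
from fastnccc.synthetic import SphereSpec, make_sphere_volume


def _result_from_map(nccc, a_opt=None):
    if a_opt is None:
        a_opt = np.full(nccc.shape, 2, dtype=np.int16)
    cfg = TemplateConfig(n=2, b=7, a_max=3)
    return NCCCResult(nccc=nccc, a_opt=a_opt, config=cfg, method_tag="scan")


class TestTopN:
    def test_single_top_is_global_argmax(self, rng):
        m = rng.random((10, 10, 10))
        det = top_n_detections(_result_from_map(m), 1)
        assert len(det) == 1
        assert det[0].center == np.unravel_index(np.argmax(m), m.shape)
        assert det[0].rank == 1

    def test_sphere_volume_rank_one_is_sphere_center(self):
        spec = SphereSpec(grid_shape=(64, 64, 64), center=(31, 29, 34),
                          radius=7)
        vol, _ = make_sphere_volume(spec)
        res = nccc_maximized(vol, TemplateConfig(n=2, b=21, a_max=10))
        det = top_n_detections(res, 1)[0]
        assert det.center == spec.center

    def test_two_separated_spheres_both_found(self):
        m = np.zeros((40, 40, 40))
        m[8, 8, 8] = 0.9
        m[30, 30, 30] = 0.9
        dets = top_n_detections(_result_from_map(m), 2)
        centers = {d.center for d in dets}
        assert centers == {(8, 8, 8), (30, 30, 30)}
        # equal scores: scan order breaks the tie
        assert dets[0].center == (8, 8, 8)

    def test_suppression_separates_detections(self, rng):
        m = rng.random((24, 24, 24))
        dets = top_n_detections(_result_from_map(m), 10, suppression_factor=2.0)
        for i, di in enumerate(dets):
            for dj in dets[i + 1:]:
                dist = np.linalg.norm(np.subtract(di.center, dj.center))
                assert dist > 2.0 * di.radius_a

    def test_scores_non_increasing_in_rank(self, rng):
        m = rng.random((20, 20, 20))
        dets = top_n_detections(_result_from_map(m), 8)
        scores = [d.score for d in dets]
        assert scores == sorted(scores, reverse=True)

    def test_exhausted_map_returns_short_list(self):
        m = np.zeros((9, 9, 9))
        m[4, 4, 4] = 1.0
        dets = top_n_detections(_result_from_map(
            m, a_opt=np.full(m.shape, 3, dtype=np.int16)), 100,
            suppression_factor=3.0)
        assert len(dets) < 100


class TestLabels:
    def test_zero_detections_give_empty_label(self):
        label = detections_to_label([], 0, 1.61, (8, 8, 8))
        assert label.sum() == 0

    def test_sphere_voxel_count_matches_enumeration(self):
        det = Detection(center=(10, 10, 10), radius_a=3.0, score=1.0, rank=1)
        label = detections_to_label([det], 1, 1.0, (21, 21, 21))
        count = sum(1 for idx in np.ndindex(21, 21, 21)
                    if np.linalg.norm(np.subtract(idx, (10, 10, 10))) <= 3.0)
        assert int(label.sum()) == count

    def test_overlapping_spheres_union_without_double_count(self):
        d1 = Detection(center=(10, 10, 10), radius_a=3.0, score=1.0, rank=1)
        d2 = Detection(center=(11, 10, 10), radius_a=3.0, score=0.9, rank=2)
        both = detections_to_label([d1, d2], 2, 1.0, (21, 21, 21))
        only1 = detections_to_label([d1], 1, 1.0, (21, 21, 21))
        only2 = detections_to_label([d2], 1, 1.0, (21, 21, 21))
        assert (both == (only1 | only2)).all()

    def test_clipped_at_grid_boundary(self):
        det = Detection(center=(0, 0, 0), radius_a=3.0, score=1.0, rank=1)
        label = detections_to_label([det], 1, 1.0, (6, 6, 6))
        assert label[0, 0, 0]
        assert label.sum() < 123  # full ball of radius 3 has 123 lattice points


class TestTpfFpf:
    def test_identical_labels_are_perfect(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[2:4, 2:4, 2:4] = True
        assert tpf_fpf(m, m) == (100.0, 0.0)

    def test_disjoint_labels_are_total_miss(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        a[0, 0, 0] = True
        b[5, 5, 5] = True
        assert tpf_fpf(a, b) == (0.0, 100.0)

    def test_subcube_counts(self):
        manual = np.zeros((8, 8, 8), dtype=bool)
        manual[2:5, 2:5, 2:5] = True          # 27 voxels
        auto = np.zeros((8, 8, 8), dtype=bool)
        auto[2:4, 2:4, 2:4] = True            # 8 voxels inside
        tpf, fpf = tpf_fpf(auto, manual)
        assert tpf == pytest.approx(100.0 * 8 / 27)
        assert fpf == 0.0

    def test_empty_manual_label_rejected(self):
        with pytest.raises(ValueError):
            tpf_fpf(np.ones((4, 4, 4), dtype=bool),
                    np.zeros((4, 4, 4), dtype=bool))

    def test_empty_automatic_label_warns_and_reports_zero_fpf(self):
        manual = np.zeros((4, 4, 4), dtype=bool)
        manual[1, 1, 1] = True
        with pytest.warns(UserWarning):
            tpf, fpf = tpf_fpf(np.zeros((4, 4, 4), dtype=bool), manual)
        assert (tpf, fpf) == (0.0, 0.0)


class TestCurve:
    def test_tpf_monotone_and_matches_recompute(self, rng):
        m = rng.random((24, 24, 24))
        res = _result_from_map(m)
        manual = np.zeros(m.shape, dtype=bool)
        manual[6:15, 6:15, 6:15] = True
        curve = tpf_fpf_curve(res, manual, n_top_max=6, radius_multiplier=1.61)
        assert (np.diff(curve["tpf"]) >= 0).all()
        # recompute every point from scratch with cumulative labels
        dets = top_n_detections(res, 6)
        for _, row in curve.iterrows():
            k = int(row["n_top"])
            label = detections_to_label(dets, k, 1.61, m.shape)
            t, f = tpf_fpf(label, manual)
            assert row["tpf"] == pytest.approx(t)
            assert row["fpf"] == pytest.approx(f)

    def test_perfect_single_lesion_curve(self):
        m = np.full((20, 20, 20), -1.0)
        m[10, 10, 10] = 1.0
        a_opt = np.full(m.shape, 2, dtype=np.int16)
        res = _result_from_map(m, a_opt)
        manual = detections_to_label(
            [Detection(center=(10, 10, 10), radius_a=2.0, score=1.0, rank=1)],
            1, 1.0, m.shape)
        curve = tpf_fpf_curve(res, manual, n_top_max=3, radius_multiplier=1.0)
        assert curve["tpf"].iloc[0] == 100.0
        assert (curve["tpf"] == 100.0).all()


class TestFrame:
    def test_table_columns_and_order(self):
        dets = [Detection(center=(1, 2, 3), radius_a=2.0, score=0.5, rank=1)]
        frame = detections_to_frame(dets)
        assert list(frame.columns) == ["rank", "x", "y", "z", "a_opt", "score"]
        assert frame.iloc[0]["x"] == 1
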