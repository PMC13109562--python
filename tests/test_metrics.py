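import numpy as np
import pytest

from denseleaf.boxes import BoundingBox, ScoredBox
from denseleaf.coco_io import (read_detections, read_ground_truth,
                               write_detections, write_ground_truth)
from denseleaf.metrics import (COCO_IOU_THRESHOLDS, ap_from_ranked_flags,
                               greedy_match, summarize)
from denseleaf.scenes import SceneSpec, annotate_scene, generate_scenes
from .conftest import random_box
from .oracles import coco_eval_oracle


def jittered(box: BoundingBox, dx: float) -> BoundingBox:
    return BoundingBox(box.x_min + dx, box.y_min + dx, box.x_max + dx, box.y_max + dx)


class TestGreedyMatch:
    def test_perfect_detections_all_tp(self, rng):
        gts = [random_box(rng) for _ in range(5)]
        dets = [ScoredBox(g, 0.9) for g in gts]
        flags, fn = greedy_match(dets, gts, 0.5)
        assert flags.all() and fn == 0

    def test_no_detections_all_fn(self, rng):
        gts = [random_box(rng) for _ in range(3)]
        flags, fn = greedy_match([], gts, 0.5)
        assert flags.size == 0 and fn == 3

    def test_hit_miss_hit_sequence(self):
        gts = [BoundingBox(0, 0, 10, 10), BoundingBox(50, 50, 60, 60)]
        dets = [ScoredBox(BoundingBox(0, 0, 10, 10), 0.9),     # hit gt 0
                ScoredBox(BoundingBox(90, 90, 99, 99), 0.8),   # miss
                ScoredBox(BoundingBox(50, 50, 60, 60), 0.7)]   # hit gt 1
        flags, fn = greedy_match(dets, gts, 0.5)
        assert flags.tolist() == [True, False, True] and fn == 0

    def test_each_gt_matched_once(self):
        gt = [BoundingBox(0, 0, 10, 10)]
        dets = [ScoredBox(BoundingBox(0, 0, 10, 10), 0.9),
                ScoredBox(BoundingBox(0, 0, 10, 10), 0.8)]
        flags, fn = greedy_match(dets, gt, 0.5)
        assert flags.tolist() == [True, False] and fn == 0

    def test_max_dets_caps_the_list(self):
        gt = [BoundingBox(0, 0, 10, 10)]
        dets = [ScoredBox(BoundingBox(90, 90, 99, 99), 0.9),
                ScoredBox(BoundingBox(0, 0, 10, 10), 0.8)]
        flags, fn = greedy_match(dets, gt, 0.5, max_dets=1)
        assert flags.tolist() == [False] and fn == 1


class TestAveragePrecision:
    def test_all_tp_covering_all_gts(self):
        assert ap_from_ranked_flags([True, True], 2) == pytest.approx(1.0)

    def test_all_fp(self):
        assert ap_from_ranked_flags([False, False], 2) == 0.0

    def test_zero_gt_with_detections(self):
        assert ap_from_ranked_flags([False], 0) == 0.0

    def test_worked_tp_fp_tp_sequence(self):
        """Envelope at 101 recall points: 51 points at 1.0, 50 at 2/3."""
        expected = (51 * 1.0 + 50 * (2.0 / 3.0)) / 101
        assert ap_from_ranked_flags([True, False, True], 2) == pytest.approx(expected)
        assert expected == pytest.approx(0.8350, abs=5e-5)

    def test_continuous_mode_literal_integral(self):
        # area under the envelope: 0.5 * 1.0 + 0.5 * 2/3
        got = ap_from_ranked_flags([True, False, True], 2, interpolation="continuous")
        assert got == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_flipping_tp_to_fp_never_raises_ap(self, rng):
        for _ in range(50):
            flags = rng.uniform(size=8) < 0.5
            num_gt = int(flags.sum()) + int(rng.integers(0, 3))
            base = ap_from_ranked_flags(flags, num_gt)
            tp_positions = np.flatnonzero(flags)
            if tp_positions.size == 0:
                continue
            flipped = flags.copy()
            flipped[rng.choice(tp_positions)] = False
            assert ap_from_ranked_flags(flipped, num_gt) <= base + 1e-12


def scene_eval_fixture(num_scenes=5, jitter_seed=7):
    """Scenes + noisy detections exercising hits, misses and false alarms."""
    spec = SceneSpec(width=96, height=96, mean_instances=12.0,
                     semi_major_range=(8.0, 14.0), semi_minor_range=(5.0, 9.0),
                     seed=500)
    scenes = generate_scenes(spec, num_scenes)
    rng = np.random.default_rng(jitter_seed)
    gts, dets = {}, {}
    for idx, scene in enumerate(scenes, start=1):
        boxes = annotate_scene(scene.instances, scene.spec.min_visible_fraction)
        gts[idx] = boxes
        img_dets = []
        for b in boxes:
            if rng.uniform() < 0.85:  # detected, with localization noise
                img_dets.append(ScoredBox(jittered(b, float(rng.normal(0, 2.0))),
                                          float(rng.uniform(0.3, 1.0))))
        for _ in range(rng.integers(1, 4)):  # false alarms
            x0, y0 = rng.uniform(0, 70, 2)
            img_dets.append(ScoredBox(BoundingBox(x0, y0, x0 + 15, y0 + 12),
                                      float(rng.uniform(0.0, 0.6))))
        dets[idx] = img_dets
    return dets, gts


class TestSummarize:
    def test_perfect_detector(self, rng):
        gts = {1: [random_box(rng) for _ in range(4)],
               2: [random_box(rng) for _ in range(6)]}
        dets = {i: [ScoredBox(g, 0.99) for g in boxes] for i, boxes in gts.items()}
        s = summarize(dets, gts)
        assert s.map == pytest.approx(1.0)
        assert s.map50 == pytest.approx(1.0)
        assert s.ar300 == pytest.approx(1.0)
        assert s.f1 == pytest.approx(1.0)

    def test_empty_detections_all_zero(self, rng):
        gts = {1: [random_box(rng) for _ in range(4)]}
        s = summarize({1: []}, gts)
        assert s.map == 0.0 and s.ar100 == 0.0 and s.recall == 0.0

    def test_unknown_image_id_rejected(self, rng):
        with pytest.raises(ValueError):
            summarize({99: []}, {1: [random_box(rng)]})

    def test_agrees_with_reference_coco_protocol(self):
        """Cross-implementation check on five seeded synthetic scenes."""
        dets, gts = scene_eval_fixture()
        s = summarize(dets, gts)
        ref = coco_eval_oracle(
            {i: [(d.box.to_array(), d.score) for d in v] for i, v in dets.items()},
            {i: [g.to_array() for g in v] for i, v in gts.items()},
            COCO_IOU_THRESHOLDS, max_dets=100)
        assert s.map == pytest.approx(ref["mAP"], abs=1e-6)
        assert s.map50 == pytest.approx(ref["mAP@50"], abs=1e-6)
        assert s.map75 == pytest.approx(ref["mAP@75"], abs=1e-6)
        assert s.ar100 == pytest.approx(ref["AR@100"], abs=1e-6)
        assert s.ar300 == pytest.approx(ref["AR@300"], abs=1e-6)

    def test_larger_detection_budget_never_hurts_recall(self):
        dets, gts = scene_eval_fixture(jitter_seed=11)
        s = summarize(dets, gts)
        assert s.ar300 >= s.ar100 - 1e-12

    def test_table_rendering_mentions_all_columns(self):
        dets, gts = scene_eval_fixture()
        table = summarize(dets, gts).to_table()
        for col in ("mAP", "mAP@50", "mAP@75", "AR@100", "AR@300"):
            assert col in table


class TestCocoIO:
    def test_ground_truth_round_trip(self, tmp_path, rng):
        gts = {1: [random_box(rng) for _ in range(3)], 2: []}
        path = tmp_path / "gt.json"
        write_ground_truth(gts, path, image_sizes={1: (100, 100), 2: (100, 100)})
        back = read_ground_truth(path)
        assert set(back) == {1, 2}
        for orig, rec in zip(gts[1], back[1]):
            assert np.allclose(orig.to_array(), rec.to_array())

    def test_detection_round_trip(self, tmp_path, rng):
        dets = {1: [ScoredBox(random_box(rng), 0.75)]}
        path = tmp_path / "dets.json"
        write_detections(dets, path)
        back = read_detections(path)
        assert back[1][0].score == pytest.approx(0.75)
        assert np.allclose(back[1][0].box.to_array(), dets[1][0].box.to_array())

    def test_empty_dataset_valid(self, tmp_path):
        path = tmp_path / "gt.json"
        write_ground_truth({}, path)
        assert read_ground_truth(path) == {}
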