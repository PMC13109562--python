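from dataclasses import replace

import numpy as np
import pytest

from denseleaf.assign import MatchConfig
from denseleaf.model import MiniDetector, ModelConfig, build_model
from denseleaf.scenes import annotate_scene
from denseleaf.train import TrainConfig, evaluate, split_scenes, train_smoke


def scene_inputs(scene):
    gts = annotate_scene(scene.instances, scene.spec.min_visible_fraction)
    return np.moveaxis(scene.image, -1, 0), gts


def supervised_per_gt(model, scene, aux_seed=5):
    image, gts = scene_inputs(scene)
    _, stats = model.loss(image, gts, np.random.default_rng(aux_seed))
    counts = np.zeros(len(gts), dtype=int)
    for _, g in stats["assign_ori"].pairs:
        counts[g] += 1
    for _, g in stats["assign_extra"].pairs:
        counts[g] += 1
    return counts, stats


class TestForwardContracts:
    def test_eval_mode_emits_exactly_num_queries(self, tiny_model, small_scenes):
        tiny_model.eval_mode()
        image, _ = scene_inputs(small_scenes[0])
        dets = tiny_model.infer(image, score_threshold=0.0)
        assert len(dets) == tiny_model.config.num_queries

    def test_score_threshold_one_empties_output(self, tiny_model, small_scenes):
        image, _ = scene_inputs(small_scenes[0])
        assert tiny_model.infer(image, score_threshold=1.0) == []

    def test_training_mode_adds_extra_and_injected_queries(self, tiny_model, small_scenes):
        image, gts = scene_inputs(small_scenes[0])
        tiny_model.train_mode()
        fwd = tiny_model.forward(image, gts, np.random.default_rng(3))
        n_extra = fwd["extra"].logits.shape[0]
        assert n_extra == tiny_model.config.extra_queries + fwd["num_injected"]
        assert fwd["original"].logits.shape[0] == tiny_model.config.num_queries

    def test_extra_branch_disabled_in_eval_mode(self, tiny_model, small_scenes):
        image, gts = scene_inputs(small_scenes[0])
        tiny_model.eval_mode()
        fwd = tiny_model.forward(image, gts)
        assert fwd["extra"] is None and fwd["num_injected"] == 0

    def test_eval_query_count_unchanged_by_cqr_toggle(self, tiny_model_config, small_scenes):
        image, _ = scene_inputs(small_scenes[0])
        counts = []
        for use_cqr in (True, False):
            model = MiniDetector(replace(tiny_model_config, use_cqr=use_cqr))
            model.eval_mode()
            counts.append(len(model.infer(image, score_threshold=0.0)))
        assert counts[0] == counts[1]


class TestAblationSwitches:
    def test_fpn_toggle_keeps_shapes_but_changes_features(self, tiny_model_config, small_scenes):
        image, _ = scene_inputs(small_scenes[0])
        on = MiniDetector(tiny_model_config)
        off = MiniDetector(replace(tiny_model_config, use_fpn=False))
        feats_on = on.features(image)
        feats_off = off.features(image)
        assert feats_on.shapes == feats_off.shapes
        assert not np.allclose(feats_on[0].numpy(), feats_off[0].numpy())

    def test_each_toggle_changes_training_outputs(self, tiny_model_config, small_scenes):
        image, gts = scene_inputs(small_scenes[1])

        def run(cfg):
            model = MiniDetector(cfg)
            loss, stats = model.loss(image, gts, np.random.default_rng(0))
            return float(loss.numpy()), stats

        base_loss, base_stats = run(tiny_model_config)
        for flag in ("use_fpn", "use_cqr", "use_aux"):
            loss, stats = run(replace(tiny_model_config, **{flag: False}))
            assert (loss, len(stats["assign_extra"].pairs)) != \
                   (base_loss, len(base_stats["assign_extra"].pairs))

    def test_all_off_reduces_to_one_to_one_baseline(self, tiny_model_config, small_scenes):
        image, gts = scene_inputs(small_scenes[1])
        model = MiniDetector(replace(tiny_model_config, use_fpn=False,
                                     use_cqr=False, use_aux=False))
        _, stats = model.loss(image, gts)
        assert stats["assign_extra"].pairs == []
        assert stats["num_injected"] == 0
        gt_counts = np.bincount([g for _, g in stats["assign_ori"].pairs],
                                minlength=len(gts))
        assert gt_counts.max(initial=0) <= 1


class TestCQRSupervision:
    def test_cqr_multiplies_supervision_on_crowded_scenes(self, tiny_model_config):
        """With k=4 one-to-many matching, ground truths collect >=2 queries."""
        from denseleaf.scenes import SceneSpec, generate_scenes
        spec = SceneSpec(width=64, height=64, mean_instances=30.0,
                         semi_major_range=(7.0, 12.0), semi_minor_range=(4.0, 8.0),
                         seed=303)
        scenes = generate_scenes(spec, 2)
        cqr_cfg = replace(tiny_model_config, match=MatchConfig(k=4))
        base_cfg = replace(tiny_model_config, use_cqr=False, use_aux=False)
        for scene in scenes:
            counts_cqr, _ = supervised_per_gt(MiniDetector(cqr_cfg), scene)
            counts_base, _ = supervised_per_gt(MiniDetector(base_cfg), scene)
            assert (counts_cqr >= 2).sum() > (counts_base >= 2).sum()
            assert counts_base.max(initial=0) <= 1

    def test_nms_culling_shrinks_matcher_input(self, small_scenes):
        from denseleaf.assign import cqr_compose
        from denseleaf.boxes import BoundingBox, ScoredBox, class_agnostic_nms
        image_size = (64.0, 64.0)
        gts = [BoundingBox(10, 10, 30, 30)]
        distinct = [ScoredBox(BoundingBox(5 + 12 * i, 5, 17 + 12 * i, 17), 0.5)
                    for i in range(4)]
        dup = distinct + [ScoredBox(BoundingBox(5.5, 5, 17.5, 17), 0.4)]
        kept_distinct = class_agnostic_nms(distinct, 0.7)
        kept_dup = class_agnostic_nms(dup, 0.7)
        assert len(kept_distinct) == len(distinct)   # no duplicates: nothing culled
        assert len(kept_dup) < len(dup)              # duplicate present: strict cut
        a_ori, _ = cqr_compose(dup, [], gts, MatchConfig(nms_threshold=0.7), image_size)
        assert all(p != 4 for p, _ in a_ori.pairs)


class TestTraining:
    def test_identical_seeds_identical_trajectories(self, tiny_model_config, small_scenes):
        cfg = TrainConfig(seed=2)
        runs = []
        for _ in range(2):
            model = MiniDetector(tiny_model_config)
            res = train_smoke(small_scenes, model, cfg, iterations=8,
                              evaluate_after=False)
            runs.append(res.losses)
        assert runs[0] == runs[1]

    def test_short_run_is_finite_and_logged(self, tiny_model, small_scenes, tmp_path):
        csv_path = tmp_path / "loss.csv"
        res = train_smoke(small_scenes, tiny_model, TrainConfig(seed=4),
                          iterations=10, log_csv=csv_path, evaluate_after=False)
        assert len(res.losses) == 10
        assert np.isfinite(res.losses).all()
        assert csv_path.read_text().count("\n") == 11  # header + 10 rows

    def test_split_is_deterministic_and_disjoint(self, small_scenes):
        train_a, val_a = split_scenes(small_scenes, 0.8, seed=9)
        train_b, val_b = split_scenes(small_scenes, 0.8, seed=9)
        assert [id(s) for s in train_a] == [id(s) for s in train_b]
        assert len(train_a) + len(val_a) == len(small_scenes)
        assert not set(map(id, train_a)) & set(map(id, val_a))

    def test_evaluate_returns_summary(self, tiny_model, small_scenes):
        summary = evaluate(small_scenes[:2], tiny_model)
        assert 0.0 <= summary.map <= 1.0
        assert summary.ar300 >= summary.ar100 - 1e-12


def test_build_model_and_config_validation():
    model = build_model(ModelConfig(channels=16, num_levels=2, num_queries=8))
    assert model.config.extra_queries == 8
    with pytest.raises(ValueError):
        ModelConfig(num_queries=0)
    with pytest.raises(ValueError):
        ModelConfig(channels=12)
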