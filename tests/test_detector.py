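"""Matching strategy, multibox loss, hard negatives, image-level staging."""

import numpy as np
import pytest

from endospectra import (
    BoundingBox,
    Detection,
    image_level_call,
    match_boxes,
    multibox_loss,
    select_hard_negatives,
)
from endospectra.boxes import DefaultBox, DefaultBoxSet, encode_offsets
from endospectra.detector import (
    N_CLASSES,
    GroundTruthStubScorer,
    decode_detections,
    stage_class_index,
)
from endospectra.errors import ConfigurationError
from endospectra.stages import StageLabel


def _default_set(boxes):
    return DefaultBoxSet(
        boxes=[DefaultBox(box=b, feature_map_index=0, scale=0.5, aspect_ratio=1.0)
               for b in boxes],
        image_size=(100, 100))


@pytest.fixture()
def simple_defaults():
    # IoUs against gt (0,0,10,10): first 0.9+, second ~0.4, third 0
    return _default_set([
        BoundingBox(0, 0, 10, 10.5),
        BoundingBox(0, 0, 10, 4.2),
        BoundingBox(50, 50, 60, 60),
    ])


GT = (BoundingBox(0, 0, 10, 10), StageLabel.INVASIVE_CANCER)


class TestMatching:
    def test_threshold_rule_with_high_and_low_iou(self, simple_defaults):
        m = match_boxes(simple_defaults, [GT], threshold=0.5)
        assert m.n_positives == 1
        assert m.gt_index.tolist() == [0, -1, -1]

    def test_argmax_default_positive_even_below_threshold(self):
        defaults = _default_set([BoundingBox(0, 0, 10, 3),   # IoU 0.3
                                 BoundingBox(30, 30, 40, 40)])
        m = match_boxes(defaults, [GT], threshold=0.5)
        assert m.n_positives == 1
        assert m.gt_index[0] == 0

    def test_no_ground_truths_gives_zero_positives(self, simple_defaults):
        m = match_boxes(simple_defaults, [], threshold=0.5)
        assert m.n_positives == 0

    def test_every_gt_has_a_positive_property(self, rng):
        """The argmax rule guarantees >=1 positive per ground truth at any
        threshold."""
        boxes = [BoundingBox(x, y, x + w, y + h)
                 for x, y, w, h in rng.uniform(1, 40, (30, 4))]
        defaults = _default_set(boxes)
        for trial in range(10):
            gts = [(BoundingBox(x, y, x + w, y + h), StageLabel.INVASIVE_CANCER)
                   for x, y, w, h in rng.uniform(1, 40, (3, 4))]
            for thr in (0.3, 0.5, 0.9):
                m = match_boxes(defaults, gts, threshold=thr)
                matched = set(m.gt_index[m.gt_index >= 0])
                assert matched == {0, 1, 2}

    def test_empty_defaults_rejected(self):
        with pytest.raises(ConfigurationError):
            match_boxes(DefaultBoxSet(boxes=[], image_size=(10, 10)), [GT])


class TestMultiboxLoss:
    def _loss_inputs(self, defaults, gts, match, perfect=False, margin=20.0):
        D = len(defaults)
        conf = np.zeros((D, N_CLASSES))
        offsets = np.zeros((D, 4))
        for i in range(D):
            if match.gt_index[i] >= 0:
                gt_box, gt_stage = gts[match.gt_index[i]]
                if perfect:
                    conf[i, stage_class_index(gt_stage)] = margin
                    offsets[i] = encode_offsets(gt_box, defaults.boxes[i].box)
            else:
                if perfect:
                    conf[i, 0] = margin
        return conf, offsets

    def test_zero_positives_defines_loss_zero(self, simple_defaults):
        m = match_boxes(simple_defaults, [], threshold=0.5)
        out = multibox_loss(np.ones((3, N_CLASSES)), np.ones((3, 4)), m, [],
                            simple_defaults)
        assert (out.total, out.confidence, out.localization) == (0.0, 0.0, 0.0)

    def test_substitution_identity(self, simple_defaults):
        """total = (Lconf + alpha*Lloc)/N; e.g. (2 + 1*1)/2 = 1.5."""
        m = match_boxes(simple_defaults, [GT], threshold=0.01)
        out = multibox_loss(*self._loss_inputs(simple_defaults, [GT], m), m, [GT],
                            simple_defaults, alpha=1.0)
        assert out.total == pytest.approx(
            (out.confidence + 1.0 * out.localization) / out.n_positives)
        assert (2.0 + 1.0 * 1.0) / 2 == 1.5  # the worked substitution

    def test_perfect_predictions_drive_loss_to_zero(self, simple_defaults):
        m = match_boxes(simple_defaults, [GT], threshold=0.5)
        conf, offsets = self._loss_inputs(simple_defaults, [GT], m, perfect=True)
        out = multibox_loss(conf, offsets, m, [GT], simple_defaults)
        assert out.localization == 0.0
        assert out.confidence < 1e-6  # confident limit

    def test_duplication_invariance(self, rng):
        """k-fold duplication of all boxes/terms leaves the total unchanged."""
        boxes = [BoundingBox(x, y, x + w, y + h)
                 for x, y, w, h in rng.uniform(1, 40, (6, 4))]
        defaults = _default_set(boxes)
        gts = [GT]
        m = match_boxes(defaults, gts, threshold=0.3)
        conf = rng.standard_normal((6, N_CLASSES))
        offs = rng.standard_normal((6, 4))
        base = multibox_loss(conf, offs, m, gts, defaults)
        k = 3
        defaults_k = _default_set(boxes * k)
        from endospectra.detector import MatchAssignment
        m_k = MatchAssignment(gt_index=np.tile(m.gt_index, k))
        out = multibox_loss(np.tile(conf, (k, 1)), np.tile(offs, (k, 1)),
                            m_k, gts, defaults_k)
        assert out.n_positives == k * base.n_positives
        assert out.total == pytest.approx(base.total, rel=1e-9)

    def test_negative_alpha_rejected(self, simple_defaults):
        m = match_boxes(simple_defaults, [GT])
        with pytest.raises(ConfigurationError):
            multibox_loss(np.zeros((3, N_CLASSES)), np.zeros((3, 4)), m, [GT],
                          simple_defaults, alpha=-1.0)


class TestHardNegatives:
    def _assignment(self, n_pos, n_neg):
        from endospectra.detector import MatchAssignment
        gt_index = np.array([0] * n_pos + [-1] * n_neg)
        return MatchAssignment(gt_index=gt_index)

    def test_ratio_count_rule(self):
        m = self._assignment(2, 10)
        losses = np.arange(12, dtype=float)
        assert len(select_hard_negatives(losses, m, ratio=3.0)) == 6

    def test_fewer_negatives_than_quota_keeps_all(self):
        m = self._assignment(2, 4)
        out = select_hard_negatives(np.ones(6), m, ratio=3.0)
        assert len(out) == 4

    def test_equal_losses_keep_lowest_indices(self):
        m = self._assignment(1, 8)
        out = select_hard_negatives(np.ones(9), m, ratio=3.0)
        assert out.tolist() == [1, 2, 3]  # first three negative indices

    def test_selects_highest_loss_negatives(self):
        m = self._assignment(1, 5)
        losses = np.array([0.0, 1.0, 5.0, 3.0, 4.0, 2.0])
        assert set(select_hard_negatives(losses, m, ratio=3.0).tolist()) == {2, 3, 4}


class TestImageLevelCall:
    def test_no_detections_is_normal(self):
        assert image_level_call([]) is StageLabel.NORMAL

    def test_below_floor_is_normal(self):
        d = Detection(BoundingBox(0, 0, 5, 5), StageLabel.INVASIVE_CANCER, 0.4)
        assert image_level_call([d], score_floor=0.5) is StageLabel.NORMAL

    def test_single_invasive_detection(self):
        d = Detection(BoundingBox(0, 0, 5, 5), StageLabel.INVASIVE_CANCER, 0.9)
        assert image_level_call([d]) is StageLabel.INVASIVE_CANCER

    def test_tie_breaks_to_more_severe_stage(self):
        b = BoundingBox(0, 0, 5, 5)
        dets = [Detection(b, StageLabel.LOW_GRADE_DYSPLASIA, 0.8),
                Detection(b, StageLabel.HIGH_GRADE_DYSPLASIA, 0.8)]
        assert image_level_call(dets) is StageLabel.HIGH_GRADE_DYSPLASIA


class TestStubScorer:
    def test_stub_detections_recover_ground_truth(self):
        from endospectra.boxes import generate_default_boxes, small_test_spec
        defaults = generate_default_boxes((96, 96), small_test_spec())
        gts = [(BoundingBox(20, 20, 50, 44), StageLabel.HIGH_GRADE_DYSPLASIA)]
        stub = GroundTruthStubScorer(gts)
        conf, offs = stub.score(np.zeros((96, 96, 3)), defaults)
        dets = decode_detections(conf, offs, defaults)
        assert len(dets) == 1
        assert dets[0].stage is StageLabel.HIGH_GRADE_DYSPLASIA
        assert np.allclose(dets[0].box.as_tuple(), (20, 20, 50, 44), atol=1e-4)
        assert image_level_call(dets) is StageLabel.HIGH_GRADE_DYSPLASIA
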