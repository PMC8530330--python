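import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupilkinetics import (
    GroundTruthAnnotation,
    GTInterval,
    MatchConfig,
    evaluate,
    evaluate_by_intensity,
    fig7_fixture,
    harmonic_mean,
    iou_threshold,
    match,
    read_ground_truth,
    write_ground_truth,
)
from pupilkinetics.errors import AnnotationError

NO_FILTER = MatchConfig(apply_iou_filter=False)
FPS = 25.0


def match_oracle(preds, gts, fps, containment, apply_filter):
    """Exhaustive O(n*m) interval-intersection re-implementation."""

    def inter(a, b):
        return max(0, min(a[1], b[1]) - max(a[0], b[0]))

    def iou(a, b):
        u = (a[1] - a[0]) + (b[1] - b[0]) - inter(a, b)
        return inter(a, b) / u if u else 0.0

    retained = list(preds)
    if apply_filter and preds and gts:
        gtl = sum(e - s for s, e in gts) / len(gts) / fps
        pl = sum(e - s for s, e in preds) / len(preds) / fps
        tr = min(gtl, pl) / max(gtl, pl)
        retained = [p for p in preds if max(iou(p, g) for g in gts) > tr]
    tp = 0
    detected_by = []
    for g in gts:
        hits = [p for p in retained if inter(p, g) >= containment * (g[1] - g[0])]
        if hits:
            tp += 1
            detected_by.extend(hits)
    pc = len(set(detected_by))
    return tp, len(gts) - tp, len(retained) - pc, pc


def random_case(rng):
    n_gt = int(rng.integers(1, 8))
    starts = np.sort(rng.choice(1000, size=n_gt, replace=False)) * 30
    gts = [(int(s), int(s + rng.integers(10, 40))) for s in starts]
    n_p = int(rng.integers(0, 10))
    preds = []
    for _ in range(n_p):
        s = int(rng.integers(0, 30000))
        preds.append((s, s + int(rng.integers(5, 400))))
    return preds, gts


class TestIouThreshold:
    def test_equal_lengths_give_one(self):
        assert iou_threshold(1.5, 1.5) == 1.0

    def test_short_gt_long_predictions(self):
        assert iou_threshold(1.0, 10.2) == pytest.approx(1.0 / 10.2)

    def test_symmetric_ratio(self):
        assert iou_threshold(2.0, 4.0) == 0.5
        assert iou_threshold(4.0, 2.0) == 0.5

    def test_non_positive_raises(self):
        with pytest.raises(ValueError):
            iou_threshold(0.0, 1.0)


class TestWorkedExample:
    """The three-prediction walkthrough that pins down the metric arithmetic."""

    def test_exact_predictions_with_one_miss(self):
        preds, gt = fig7_fixture("pred1")
        r = evaluate(preds, gt, NO_FILTER, FPS)
        assert (r.tp, r.fn, r.fp, r.pc) == (3, 1, 0, 3)
        assert r.recall == 0.75
        assert r.precision == 1.0
        assert r.gtcr == 1.0
        assert r.h == pytest.approx(0.90)

    def test_one_blanket_prediction_plus_two_strays(self):
        preds, gt = fig7_fixture("pred2")
        r = evaluate(preds, gt, NO_FILTER, FPS)
        assert (r.tp, r.fn, r.fp, r.pc) == (3, 1, 2, 1)
        assert r.precision == pytest.approx(1 / 3)
        assert r.gtcr == pytest.approx(1 / 3)
        assert r.h == pytest.approx(9 / 22)  # 40.9 %

    def test_single_blanket_prediction(self):
        preds, gt = fig7_fixture("pred3")
        r = evaluate(preds, gt, NO_FILTER, FPS)
        assert (r.recall, r.precision, r.gtcr) == (1.0, 1.0, 0.25)
        assert r.h == 0.5

    def test_iou_filter_would_drop_the_blanket_prediction(self):
        preds, gt = fig7_fixture("pred3")
        r = evaluate(preds, gt, MatchConfig(apply_iou_filter=True), FPS)
        assert r.tp == 0 and r.pc == 0


class TestMatch:
    def test_perfect_predictions(self):
        gt = GroundTruthAnnotation([GTInterval(10, 20), GTInterval(40, 55)])
        m = match([(10, 20), (40, 55)], gt, NO_FILTER, FPS)
        assert (m.tp, m.fn, m.fp, m.pc) == (2, 0, 0, 2)
        assert m.assignment == {0: [0], 1: [1]}

    @pytest.mark.parametrize("apply_filter", [False, True])
    @pytest.mark.parametrize("containment", [1.0, 0.5])
    def test_counts_match_exhaustive_oracle(self, rng, apply_filter, containment):
        cfg = MatchConfig(apply_iou_filter=apply_filter, containment_fraction=containment)
        for _ in range(100):
            preds, gts = random_case(rng)
            gt = GroundTruthAnnotation([GTInterval(s, e) for s, e in gts])
            m = match(preds, gt, cfg, FPS)
            assert (m.tp, m.fn, m.fp, m.pc) == match_oracle(
                sorted(preds), gts, FPS, containment, apply_filter
            )
            assert m.tp + m.fn == len(gts)
            assert m.pc + m.fp == len(m.retained)

    def test_spurious_prediction_only_lowers_precision(self):
        gt = GroundTruthAnnotation([GTInterval(10, 20), GTInterval(40, 55)])
        base = evaluate([(10, 20), (40, 55)], gt, NO_FILTER, FPS)
        spiked = evaluate([(10, 20), (40, 55), (500, 520)], gt, NO_FILTER, FPS)
        assert spiked.recall == base.recall
        assert spiked.gtcr == base.gtcr
        assert spiked.precision < base.precision

    def test_overlapping_ground_truth_rejected(self):
        with pytest.raises(AnnotationError):
            GroundTruthAnnotation([GTInterval(10, 30), GTInterval(25, 40)])


class TestEvaluate:
    def test_no_predictions_all_metrics_zero(self):
        gt = GroundTruthAnnotation([GTInterval(10, 20)])
        r = evaluate([], gt, NO_FILTER, FPS)
        assert (r.recall, r.precision, r.gtcr, r.h) == (0.0, 0.0, 0.0, 0.0)

    def test_gtcr_never_exceeds_one_for_disjoint_predictions(self, rng):
        for _ in range(50):
            preds, gts = random_case(rng)
            # enforce disjoint predictions, as the detector produces
            preds = sorted(preds)
            disjoint = []
            for p in preds:
                if not disjoint or p[0] >= disjoint[-1][1]:
                    disjoint.append(p)
            gt = GroundTruthAnnotation([GTInterval(s, e) for s, e in gts])
            r = evaluate(disjoint, gt, NO_FILTER, FPS)
            assert r.gtcr <= 1.0

    def test_pl_is_mean_retained_duration(self):
        gt = GroundTruthAnnotation([GTInterval(10, 35)])
        r = evaluate([(10, 35), (100, 150)], gt, NO_FILTER, FPS)
        assert r.pl_seconds == pytest.approx((25 + 50) / 2 / FPS)
        assert r.gtl_seconds == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        r=st.floats(0.01, 1.0),
        p=st.floats(0.01, 1.0),
        g=st.floats(0.01, 1.0),
    )
    def test_harmonic_mean_closed_form(self, r, p, g):
        expected = 3.0 * r * p * g / (p * g + r * g + r * p)
        assert harmonic_mean(r, p, g) == pytest.approx(expected, abs=1e-12)
        assert min(r, p, g) - 1e-12 <= harmonic_mean(r, p, g) <= max(r, p, g) + 1e-12

    def test_harmonic_mean_zero_component(self):
        assert harmonic_mean(0.0, 0.5, 0.5) == 0.0


class TestEvaluateByIntensity:
    def make(self):
        gt = GroundTruthAnnotation(
            [
                GTInterval(10, 20, intensity="weak"),
                GTInterval(100, 120, intensity="strong"),
                GTInterval(200, 230, intensity="medium"),
            ]
        )
        return gt

    def test_all_groups_equals_plain_evaluate(self):
        gt = self.make()
        preds = [(10, 20), (100, 120)]
        full = evaluate(preds, gt, NO_FILTER, FPS)
        grouped = evaluate_by_intensity(
            preds, gt, NO_FILTER, FPS, ["weak", "medium", "strong"]
        )
        assert grouped.to_dict() == full.to_dict()

    def test_strong_only_recall(self):
        gt = GroundTruthAnnotation(
            [GTInterval(10, 20, intensity="weak"), GTInterval(100, 120, intensity="strong")]
        )
        r = evaluate_by_intensity([(100, 120)], gt, NO_FILTER, FPS, ["strong"])
        assert r.recall == 1.0

    def test_matches_manual_prefilter_oracle(self, rng):
        gt = self.make()
        preds, _ = random_case(rng)
        manual = GroundTruthAnnotation(
            [g for g in gt.intervals if g.intensity in ("medium", "strong")]
        )
        a = evaluate_by_intensity(preds, gt, NO_FILTER, FPS, ["medium", "strong"])
        b = evaluate(preds, manual, NO_FILTER, FPS)
        assert a.to_dict() == b.to_dict()

    def test_empty_groups_rejected(self):
        with pytest.raises(AnnotationError):
            evaluate_by_intensity([], self.make(), NO_FILTER, FPS, [])


def test_ground_truth_json_round_trip(tmp_path):
    gt = GroundTruthAnnotation(
        [
            GTInterval(10, 35, intensity="strong", clarity="unclear"),
            GTInterval(100, 125, intensity="weak"),
        ]
    )
    path = tmp_path / "gt.json"
    write_ground_truth(gt, 25.0, path)
    back, fps = read_ground_truth(path)
    assert fps == 25.0
    assert back.intervals == gt.intervals
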