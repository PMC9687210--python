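import itertools

import numpy as np
import pytest

from cxrnodule.detection import Detection, DetectionSet
from cxrnodule.evaluation import (
    DEFAULT_STRATA,
    GroundTruthNodule,
    froc,
    match_detections,
    read_ground_truth,
    sensitivity_by_size,
    summarize_sizes,
    write_ground_truth,
)
from cxrnodule.lung_roi import RoiBox


def _truth(image_id, cx, cy, d_mm=15.0, half=10):
    return GroundTruthNodule(
        image_id, cx, cy, d_mm, RoiBox(int(cx) - half, int(cy) - half, int(cx) + half, int(cy) + half)
    )


def _det(x0, y0, x1, y1, score):
    return Detection(RoiBox(x0, y0, x1, y1), score, "toy")


def brute_force_match(dets, truths):
    """Oracle: enumerate all detection->truth assignments, maximize hit
    count then total matched score; FPs are detections containing no
    truth center."""
    feasible = [
        [d.box.contains_point(t.center_x, t.center_y) for t in truths] for d in dets
    ]
    best = (0, -1.0)
    n = len(dets)
    choices = [list(range(len(truths))) + [None] for _ in range(n)]
    for assign in itertools.product(*choices):
        used = [a for a in assign if a is not None]
        if len(used) != len(set(used)):
            continue
        if any(a is not None and not feasible[i][a] for i, a in enumerate(assign)):
            continue
        hits = len(used)
        score = sum(dets[i].score for i, a in enumerate(assign) if a is not None)
        best = max(best, (hits, score))
    n_fp = sum(1 for i in range(n) if not any(feasible[i]))
    return best[0], n_fp


class TestMatchDetections:
    def test_center_in_box_is_a_hit(self):
        t = _truth("i", 50, 50)
        hits, fps = match_detections(DetectionSet("i", (_det(45, 45, 55, 55, 0.9),)), [t])
        assert hits[0] is not None and not fps

    def test_surplus_hit_is_not_a_false_positive(self):
        t = _truth("i", 50, 50)
        ds = DetectionSet("i", (_det(45, 45, 55, 55, 0.9), _det(40, 40, 60, 60, 0.2)))
        hits, fps = match_detections(ds, [t])
        assert hits[0].score == 0.9
        assert fps == []

    def test_miss_is_a_false_positive(self):
        t = _truth("i", 50, 50)
        hits, fps = match_detections(DetectionSet("i", (_det(0, 0, 10, 10, 0.9),)), [t])
        assert hits[0] is None and len(fps) == 1

    def test_image_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            match_detections(DetectionSet("a", ()), [_truth("b", 50, 50)])

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(120):
            n_t = int(rng.integers(0, 5))
            n_d = int(rng.integers(0, 7))
            truths = [
                _truth("i", int(x), int(y), half=int(h))
                for x, y, h in zip(
                    rng.integers(20, 80, n_t), rng.integers(20, 80, n_t), rng.integers(5, 20, n_t)
                )
            ]
            dets = tuple(
                _det(int(x), int(y), int(x) + int(w), int(y) + int(w), float(s))
                for x, y, w, s in zip(
                    rng.integers(0, 80, n_d),
                    rng.integers(0, 80, n_d),
                    rng.integers(5, 40, n_d),
                    rng.uniform(0, 1, n_d),
                )
            )
            hits, fps = match_detections(DetectionSet("i", dets), truths)
            bf_hits, bf_fp = brute_force_match(dets, truths)
            assert sum(v is not None for v in hits.values()) == bf_hits
            assert len(fps) == bf_fp


class TestFroc:
    def test_two_image_worked_example(self):
        truths = [_truth("A", 50, 50)]
        sets = [
            DetectionSet("A", (_det(45, 45, 55, 55, 0.05),)),
            DetectionSet("B", (_det(0, 0, 10, 10, 0.02),)),
        ]
        curve = froc(sets, truths, thresholds=[0.1, 0.05, 0.02])
        assert [(p.threshold, p.sensitivity, p.fp_per_image) for p in curve.points] == [
            (0.1, 0.0, 0.0),
            (0.05, 1.0, 0.0),
            (0.02, 1.0, 0.5),
        ]

    def test_all_scores_below_ladder_gives_zero_area(self):
        truths = [_truth("A", 50, 50)]
        sets = [DetectionSet("A", (_det(45, 45, 55, 55, 1e-6),))]
        curve = froc(sets, truths, thresholds=[0.1, 0.01])
        assert all(p.sensitivity == 0 and p.fp_per_image == 0 for p in curve.points)
        assert curve.area == 0.0

    def test_perfect_detector_normalizes_to_unit_area(self):
        truths = [_truth("A", 50, 50), _truth("B", 30, 30)]
        sets = [
            DetectionSet("A", (_det(45, 45, 55, 55, 0.99),)),
            DetectionSet("B", (_det(25, 25, 35, 35, 0.98),)),
        ]
        assert froc(sets, truths).area == 1.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="empty ground-truth"):
            froc([DetectionSet("A", ())], [])

    def test_monotone_in_threshold_on_random_sets(self, rng):
        truths, sets = [], []
        for i in range(15):
            iid = f"im{i}"
            truths.append(_truth(iid, 50, 50))
            dets = tuple(
                _det(int(x), int(y), int(x) + 20, int(y) + 20, float(s))
                for x, y, s in zip(
                    rng.integers(20, 70, 4), rng.integers(20, 70, 4), rng.uniform(0, 0.2, 4)
                )
            )
            sets.append(DetectionSet(iid, dets))
        curve = froc(sets, truths)  # FrocCurve construction asserts monotonicity
        sens = [p.sensitivity for p in curve.points]
        fps = [p.fp_per_image for p in curve.points]
        assert sens == sorted(sens) and fps == sorted(fps)

    def test_single_threshold_matches_pooled_size_strata(self, rng):
        truths, sets = [], []
        for i in range(10):
            iid = f"im{i}"
            truths.append(_truth(iid, 50, 50, d_mm=float(rng.uniform(3, 40))))
            hit = rng.random() < 0.6
            box = _det(45, 45, 55, 55, 0.5) if hit else _det(0, 0, 10, 10, 0.5)
            sets.append(DetectionSet(iid, (box,)))
        t = 0.1
        by_size = sensitivity_by_size(sets, truths, t)
        pooled = sum(
            n * s for n, s in by_size.values() if s is not None
        ) / len(truths)
        curve = froc(sets, truths, thresholds=[t])
        assert curve.points[0].sensitivity == pytest.approx(pooled)


class TestSensitivityBySize:
    def test_all_hit_strata_report_unity(self):
        truths = [
            _truth("A", 50, 50, d_mm=5.0),
            _truth("B", 50, 50, d_mm=15.0),
            _truth("C", 50, 50, d_mm=35.0),
        ]
        sets = [DetectionSet(t.image_id, (_det(45, 45, 55, 55, 0.9),)) for t in truths]
        out = sensitivity_by_size(sets, truths, 0.1)
        assert out["<6 mm"] == (1, 1.0)
        assert out["10–20 mm"] == (1, 1.0)
        assert out[">30 mm"] == (1, 1.0)

    def test_empty_stratum_is_undefined(self):
        truths = [_truth("A", 50, 50, d_mm=15.0)]
        sets = [DetectionSet("A", ())]
        assert sensitivity_by_size(sets, truths, 0.1)["<6 mm"] == (0, None)

    def test_half_hit_stratum(self):
        truths = [_truth("A", 50, 50, d_mm=12.0), _truth("B", 50, 50, d_mm=18.0)]
        sets = [
            DetectionSet("A", (_det(45, 45, 55, 55, 0.9),)),
            DetectionSet("B", (_det(0, 0, 10, 10, 0.9),)),
        ]
        n, s = sensitivity_by_size(sets, truths, 0.1)["10–20 mm"]
        assert (n, s) == (2, 0.5)

    def test_boundary_diameter_goes_to_upper_stratum(self):
        strata = {s.label: s for s in DEFAULT_STRATA}
        assert strata["10–20 mm"].contains(10.0)
        assert not strata["6–10 mm"].contains(10.0)
        assert strata["6–10 mm"].contains(6.0)


class TestSummarizeSizes:
    def test_table_percentages(self):
        truths = (
            [_truth("x", 50, 50, d_mm=15.0)] * 260
            + [_truth("x", 50, 50, d_mm=3.0)] * 399
        )
        df = summarize_sizes(truths, 659).set_index("stratum")
        assert df.loc["10–20 mm", "percent"] == 39.5

    def test_rounding_half_away_from_zero(self):
        # 471/659 = 71.47...% -> 71.5
        truths = (
            [_truth("x", 50, 50, d_mm=25.0)] * 471
            + [_truth("x", 50, 50, d_mm=3.0)] * 188
        )
        df = summarize_sizes(truths, 659).set_index("stratum")
        assert df.loc["20–30 mm", "percent"] == 71.5

    def test_zero_count_is_zero_percent(self):
        truths = [_truth("x", 50, 50, d_mm=3.0)] * 100
        df = summarize_sizes(truths, 100).set_index("stratum")
        assert df.loc[">30 mm", "percent"] == 0.0

    def test_sum_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            summarize_sizes([_truth("x", 50, 50, d_mm=3.0)], 2)


def test_ground_truth_csv_round_trip(tmp_path):
    truths = [_truth("a", 50, 50, d_mm=12.5), _truth("b", 30, 40, d_mm=7.0, half=6)]
    p = tmp_path / "gt.csv"
    write_ground_truth(truths, p)
    assert read_ground_truth(p) == truths
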