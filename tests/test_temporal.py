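import datetime as dt
import itertools

import numpy as np
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

import cxrnodule as cx
from cxrnodule.temporal import (
    CxrRecord,
    EarlyDetectionResult,
    OverlapCounts,
    PatientTimeline,
    analyze_timeline,
    earliest_detection_days,
    median_iqr,
    overlap_counts,
    waterfall_benefit,
    wilcoxon_signed_rank,
)

D = dt.date


def _tl(pid, diag, *recs):
    return PatientTimeline(
        patient_id=pid,
        diagnosis_date=diag,
        records=tuple(CxrRecord(date=d, detected_by_reader=r, detected_by_ai=a) for d, r, a in recs),
    )


class TestEarliestDetection:
    def test_earliest_flagged_record_wins(self):
        tl = _tl(
            "p", D(2014, 1, 1),
            (D(2013, 3, 7), False, False),   # 300 days before
            (D(2013, 9, 23), False, True),   # 100 days before, AI only
        )
        assert earliest_detection_days(tl, "ai") == 100
        assert earliest_detection_days(tl, "reader") == 0

    def test_no_flags_is_zero(self):
        tl = _tl("p", D(2014, 1, 1), (D(2013, 6, 1), False, False))
        assert all(earliest_detection_days(tl, s) == 0 for s in ("reader", "ai", "combined"))

    def test_combined_takes_earlier_date(self):
        tl = _tl(
            "p", D(2014, 1, 1),
            (D(2013, 3, 7), True, False),    # reader at 300 days
            (D(2013, 9, 23), False, True),   # AI at 100 days
        )
        assert earliest_detection_days(tl, "combined") == 300

    def test_record_after_diagnosis_rejected(self):
        with pytest.raises(ValueError, match="after diagnosis"):
            _tl("p", D(2014, 1, 1), (D(2014, 2, 1), False, False))

    def test_unsorted_records_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            _tl("p", D(2014, 1, 1), (D(2013, 6, 1), False, False), (D(2013, 1, 1), False, False))


class TestOverlapCounts:
    def test_cohort_arithmetic(self):
        oc = OverlapCounts(n_total=383, n_ai=226, n_reader=203, n_both=135)
        assert (oc.n_ai_only, oc.n_reader_only, oc.n_neither) == (91, 68, 89)

    def test_full_agreement_leaves_no_exclusives(self):
        oc = OverlapCounts(n_total=10, n_ai=7, n_reader=7, n_both=7)
        assert oc.n_ai_only == 0 and oc.n_reader_only == 0 and oc.n_neither == 3

    def test_nothing_detected(self):
        oc = OverlapCounts(n_total=5, n_ai=0, n_reader=0, n_both=0)
        assert oc.n_neither == 5

    def test_counts_from_results(self):
        res = [
            EarlyDetectionResult("a", 10, 20, 20),
            EarlyDetectionResult("b", 0, 5, 5),
            EarlyDetectionResult("c", 0, 0, 0),
        ]
        oc = overlap_counts(res)
        assert (oc.n_total, oc.n_ai, oc.n_reader, oc.n_both) == (3, 2, 1, 1)
        assert oc.n_neither == 1


class TestMedianIqr:
    def test_odd_length_closed_form(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3, 2, 4)

    def test_all_zero(self):
        assert median_iqr([0, 0, 0, 0]) == (0, 0, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])

    def test_matches_sort_and_index_oracle(self, rng):
        for _ in range(30):
            days = rng.integers(0, 500, int(rng.integers(1, 40))).astype(float)
            med, q1, q3 = median_iqr(days)
            srt = np.sort(days)

            def orc(q):
                k = q * (len(srt) - 1)
                lo = int(np.floor(k))
                hi = min(lo + 1, len(srt) - 1)
                return srt[lo] + (k - lo) * (srt[hi] - srt[lo])

            assert (med, q1, q3) == pytest.approx((orc(0.5), orc(0.25), orc(0.75)))


def exact_sign_flip_p(diffs):
    """Oracle: direct 2^n enumeration over per-pair sign flips."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    lo, hi = min(w_pos, w_neg), max(w_pos, w_neg)
    n_extreme = 0
    for signs in itertools.product([False, True], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= lo + 1e-9 or w >= hi - 1e-9:
            n_extreme += 1
    return n_extreme / 2 ** len(d)


class TestWilcoxonSignedRank:
    def test_identical_samples_degenerate(self):
        r = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert r.p_value == 1.0 and r.statistic == 0.0 and r.all_zero

    def test_six_uniform_positives_closed_form(self):
        r = wilcoxon_signed_rank([2, 3, 4, 5, 6, 7], [1, 1, 1, 1, 1, 1])
        assert r.p_value == pytest.approx(0.03125)
        assert r.n_effective == 6 and r.exact

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 13))
            a = rng.integers(0, 50, n).astype(float)
            b = rng.integers(0, 50, n).astype(float)
            r = wilcoxon_signed_rank(a, b)
            assert r.p_value == pytest.approx(exact_sign_flip_p(a - b), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        checked = 0
        while checked < 20:
            a = rng.random(12) * 100
            b = rng.random(12) * 100
            r = wilcoxon_signed_rank(a, b)
            ref = scipy_wilcoxon(a, b, zero_method="wilcox", mode="exact")
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)
            checked += 1

    def test_large_sample_normal_approximation_is_close(self, rng):
        a = rng.integers(0, 400, 100).astype(float)
        b = np.maximum(a - rng.integers(0, 60, 100), 0).astype(float)
        mine = wilcoxon_signed_rank(a, b)
        ref = scipy_wilcoxon(a, b, zero_method="wilcox", correction=True, mode="approx")
        assert not mine.exact
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestWaterfallBenefit:
    def test_benefit_subtraction(self):
        res = [EarlyDetectionResult("p", 194, 303, 303)]
        entries, n_pos = waterfall_benefit(res)
        assert entries == [("p", 109)] and n_pos == 1

    def test_ai_never_detects_gives_zero_benefit(self):
        res = [EarlyDetectionResult("p", 50, 0, 50)]
        entries, n_pos = waterfall_benefit(res)
        assert entries == [("p", 0)] and n_pos == 0

    def test_positive_count_equals_counting_oracle(self):
        tls = cx.generate_timelines(cx.TimelineConfig(n_patients=120, seed=5))
        res = [analyze_timeline(tl) for tl in tls]
        _, n_pos = waterfall_benefit(res)
        oc = overlap_counts(res)
        both_ai_earlier = sum(
            1 for r in res if r.days_ai > 0 and r.days_reader > 0 and r.days_ai > r.days_reader
        )
        assert n_pos == oc.n_ai_only + both_ai_earlier


class TestGeneratedCohortInvariants:
    def test_combined_is_elementwise_max_and_median_dominates(self):
        tls = cx.generate_timelines(cx.TimelineConfig(n_patients=200, seed=17))
        res = [analyze_timeline(tl) for tl in tls]
        assert all(r.days_combined == max(r.days_reader, r.days_ai) for r in res)
        med_c = median_iqr([r.days_combined for r in res])[0]
        med_r = median_iqr([r.days_reader for r in res])[0]
        med_a = median_iqr([r.days_ai for r in res])[0]
        assert med_c >= max(med_r, med_a)

    def test_overlap_closure_identities(self):
        tls = cx.generate_timelines(cx.TimelineConfig(n_patients=150, seed=23))
        oc = overlap_counts([analyze_timeline(tl) for tl in tls])
        assert oc.n_ai_only == oc.n_ai - oc.n_both
        assert oc.n_reader_only == oc.n_reader - oc.n_both
        assert oc.n_total == oc.n_both + oc.n_ai_only + oc.n_reader_only + oc.n_neither
        assert min(oc.n_ai_only, oc.n_reader_only, oc.n_neither) >= 0


def test_timeline_csv_round_trip(tmp_path):
    tls = cx.generate_timelines(cx.TimelineConfig(n_patients=15, seed=3))
    p = tmp_path / "tl.csv"
    cx.write_timelines(tls, p)
    back = cx.read_timelines(p)
    assert back == sorted(tls, key=lambda t: t.patient_id)
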