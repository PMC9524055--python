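"""Evaluation statistics: confusion metrics, PPVs, IRA, CIs, timeliness, Wilcoxon."""

import datetime as dt
import itertools
import math

import numpy as np
import pytest
from scipy import stats

from tweetwarn.evaluate import (
    AUTOMATED,
    MANUAL,
    AlertTriage,
    ConfusionCounts,
    GeoAnnotation,
    UniqueEvent,
    confusion_metrics,
    dedup_events,
    display_round,
    geolocation_accuracy,
    ira,
    paired_time_diffs,
    ppv_general,
    ppv_specific,
    timeliness,
    wald_ci,
    wilcoxon_signed_rank,
)
from tweetwarn.geo import GeoMatch

UTC = dt.timezone.utc


def pred(country, admin1="", score=15.0):
    return GeoMatch(entry_id=-1, match_score=score, source="tweet_text", country=country, admin1=admin1)


class TestConfusionMetrics:
    def test_hand_arithmetic(self):
        m = confusion_metrics(ConfusionCounts(tp=30, fp=10, tn=40, fn=20))
        assert m.sensitivity == pytest.approx(60.0)
        assert m.specificity == pytest.approx(80.0)
        assert m.ppv == pytest.approx(75.0)
        assert display_round(m.npv) == 66.7
        assert m.prevalence == pytest.approx(50.0)

    def test_degenerate_denominators_are_nan(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.specificity == 100.0
        assert math.isnan(m.sensitivity)

    def test_fractional_counts(self):
        m = confusion_metrics(ConfusionCounts(tp=1.5, fp=0.5, tn=1, fn=1))
        assert m.ppv == pytest.approx(75.0)

    def test_consistency_identities(self):
        c = ConfusionCounts(tp=17, fp=5, tn=11, fn=9)
        m = confusion_metrics(c)
        assert m.sensitivity * (c.tp + c.fn) == pytest.approx(100 * c.tp)
        assert m.prevalence * c.total == pytest.approx(100 * (c.tp + c.fn))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=0, fp=0, tn=0, fn=0)


class TestGeolocationAccuracy:
    def test_all_correct(self):
        anns = [
            GeoAnnotation(tweet_id=f"t{i}", rater="A", gold_country="FR", predicted=pred("FR"))
            for i in range(4)
        ]
        acc, counts, metrics = geolocation_accuracy(anns, "national")
        assert acc == 100.0
        assert counts.tp == 4 and counts.fp == counts.fn == 0

    def test_disagreeing_raters_contribute_half(self):
        anns = [
            GeoAnnotation(tweet_id="t1", rater="A", gold_country="FR", predicted=pred("FR")),
            GeoAnnotation(tweet_id="t1", rater="B", gold_country="ES", predicted=pred("FR")),
            GeoAnnotation(tweet_id="t2", rater="A", gold_country="FR", predicted=pred("FR")),
            GeoAnnotation(tweet_id="t2", rater="B", gold_country="FR", predicted=pred("FR")),
        ]
        acc, _, _ = geolocation_accuracy(anns, "national")
        assert acc == pytest.approx(100 * 1.5 / 2)

    def test_subnational_needs_admin1_agreement(self):
        anns = [
            GeoAnnotation(
                tweet_id="t1",
                rater="A",
                gold_country="FR",
                gold_admin1="11",
                predicted=pred("FR", admin1="11"),
            ),
            GeoAnnotation(
                tweet_id="t2",
                rater="A",
                gold_country="FR",
                gold_admin1="11",
                predicted=pred("FR", admin1="75"),
            ),
        ]
        acc, _, _ = geolocation_accuracy(anns, "subnational")
        assert acc == 50.0

    def test_confusion_cell_convention(self):
        anns = [
            # positive hit, assigned -> tp
            GeoAnnotation(tweet_id="t1", rater="A", gold_country="FR", predicted=pred("ES")),
            # positive hit, unassigned -> fp
            GeoAnnotation(tweet_id="t2", rater="A", gold_country="FR", predicted=None),
            # negative hit, unassigned -> tn
            GeoAnnotation(tweet_id="t3", rater="A"),
            # negative hit, assigned -> fn
            GeoAnnotation(tweet_id="t4", rater="A", predicted=pred("FR")),
        ]
        _, counts, _ = geolocation_accuracy(anns, "national")
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (1, 1, 1, 1)

    def test_duplicate_pair_rejected(self):
        anns = [
            GeoAnnotation(tweet_id="t1", rater="A", gold_country="FR"),
            GeoAnnotation(tweet_id="t1", rater="A", gold_country="ES"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            geolocation_accuracy(anns, "national")


class TestPPVAndIRA:
    def test_ppv_specific_zero_events(self):
        assert ppv_specific(0, 10) == 0.0
        assert math.isnan(ppv_specific(0, 0))

    def test_ppv_general_reduces_to_specific(self):
        assert ppv_general(30, 10, 0) == ppv_specific(30, 10)

    def test_ppv_general_never_exceeds_specific(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            e, f, ne = rng.integers(0, 500, 3)
            if e + f == 0:
                continue
            assert ppv_general(e, f, ne) <= ppv_specific(e, f) + 1e-12

    def test_ira_bounds(self):
        assert ira(0, 10) == 0.0
        assert math.isnan(ira(0, 0))
        with pytest.raises(ValueError):
            ira(11, 10)

    def test_partition_of_evaluated_signals(self):
        manual_only, auto_only, both = 122, 297, 151
        total = manual_only + auto_only + both
        assert total == 570
        assert display_round(ira(auto_only + both, total)) == 78.6
        assert display_round(ira(manual_only + both, total)) == 47.9


class TestWaldCI:
    def test_hand_computation(self):
        lo, hi = wald_ci(5, 10, 0.95)
        z = 1.959963984540054
        half = z * math.sqrt(0.25 / 10)
        assert lo == pytest.approx(100 * (0.5 - half))
        assert (display_round(lo), display_round(hi)) == (19.0, 81.0)

    def test_degenerate_proportion_clips(self):
        assert wald_ci(0, 10) == (0.0, 0.0)
        assert wald_ci(10, 10) == (100.0, 100.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wald_ci(1, 0)
        with pytest.raises(ValueError):
            wald_ci(5, 4)


def triage(alert_id, status, detected_by=(), when=None, topic="hantavirus", subtopic="case-ar"):
    return AlertTriage(
        alert_id=alert_id,
        status=status,
        detected_by=frozenset(detected_by),
        validation_time=when,
        topic=topic,
        subtopic=subtopic,
    )


class TestDedupAndTimeliness:
    t0 = dt.datetime(2020, 11, 2, 10, 0, tzinfo=UTC)

    def test_same_subtopic_collapses(self):
        events = dedup_events(
            [
                triage("a1", "event", [AUTOMATED], self.t0),
                triage("a2", "event", [AUTOMATED], self.t0 + dt.timedelta(hours=5)),
            ]
        )
        assert len(events) == 1
        assert events[0].validation_times[AUTOMATED] == self.t0  # earliest kept

    def test_distinct_subtopics_stay_separate(self):
        events = dedup_events(
            [
                triage("a1", "event", [AUTOMATED], self.t0, subtopic="s1"),
                triage("a2", "event", [AUTOMATED], self.t0, subtopic="s2"),
            ]
        )
        assert len(events) == 2

    def test_event_without_subtopic_rejected(self):
        with pytest.raises(ValueError, match="subtopic"):
            dedup_events([triage("a1", "event", [AUTOMATED], self.t0, subtopic="")])

    def test_common_event_yields_one_paired_diff(self):
        events = dedup_events(
            [
                triage("a1", "event", [AUTOMATED], self.t0),
                triage("m1", "event", [MANUAL], self.t0 + dt.timedelta(hours=48)),
            ]
        )
        diffs = paired_time_diffs(events)
        assert diffs == [-48.0]

    def test_validation_time_iff_event(self):
        with pytest.raises(ValueError):
            triage("a1", "false_signal", [AUTOMATED], self.t0)
        with pytest.raises(ValueError):
            triage("a1", "event", [AUTOMATED], None)

    def test_timeliness_interpolation(self):
        med, q1, q3 = timeliness([-5, -3, -1])
        assert (med, q1, q3) == (-3, -4, -2)

    def test_timeliness_single_and_symmetric(self):
        assert timeliness([-2]) == (-2, -2, -2)
        assert timeliness([-1, 0, 1])[0] == 0

    def test_timeliness_empty_rejected(self):
        with pytest.raises(ValueError):
            timeliness([])


def brute_force_p_less(diffs):
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-9:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_all_negative_exact(self):
        w, p = wilcoxon_signed_rank([-5, -4, -3, -2, -1])
        assert w == 0 and p == pytest.approx(1 / 32)

    def test_single_diff(self):
        assert wilcoxon_signed_rank([-2]) == (0.0, 0.5)

    def test_zeros_dropped(self):
        w, p = wilcoxon_signed_rank([0, 0, -3, -1, 0])
        assert (w, p) == wilcoxon_signed_rank([-3, -1])
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0, 0])

    def test_mirror_identity(self):
        d = [-3, -2, -1, 4]
        ranks = stats.rankdata(np.abs(d))
        w_obs = stats.rankdata(np.abs(d))[np.array(d) > 0].sum()
        _, p = wilcoxon_signed_rank(d, "less")
        _, p_mirror = wilcoxon_signed_rank([-x for x in d], "less")
        # exact pmf mass at w_obs via enumeration
        n = len(d)
        mass = sum(
            1
            for signs in itertools.product((0, 1), repeat=n)
            if abs(sum(r for r, s in zip(ranks, signs) if s) - w_obs) < 1e-9
        ) / 2**n
        assert p == pytest.approx(1 - p_mirror + mass)

    @pytest.mark.parametrize("n", range(3, 13))
    def test_exact_matches_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(3):
            d = rng.normal(size=n)
            while len(np.unique(np.abs(d))) < n:
                d = rng.normal(size=n)
            _, p = wilcoxon_signed_rank(d, "less")
            assert p == pytest.approx(brute_force_p_less(d))

    def test_matches_scipy_exact(self):
        d = [-8.1, -5.2, -3.3, 2.4, -1.5, 6.6, -9.7]
        w, p = wilcoxon_signed_rank(d, "less")
        ref = stats.wilcoxon(d, alternative="less", method="exact")
        assert w == ref.statistic
        assert p == pytest.approx(ref.pvalue)

    def test_matches_scipy_approx_with_ties(self):
        d = [-5, -5, -3, -3, -2, -1, 1, 2, 2, 4, 6, -7, 8, -9, 3, 3]
        w, p = wilcoxon_signed_rank(d, "less")
        ref = stats.wilcoxon(d, alternative="less", method="approx", correction=True)
        assert w == ref.statistic
        assert p == pytest.approx(ref.pvalue)
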