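"""Surveillance-evaluation statistics.

Covers both evaluation layers of an event-based surveillance system:

* geolocation quality — per-tweet accuracy against expert annotation, and
  the confusion-matrix metrics for *deciding which tweets contain an
  extractable location*.  A "positive hit" is a tweet from which the human
  rater could extract a location; among positive hits a tweet counts as a
  true positive when the system assigned a location and a false positive
  when it did not, while among negative hits it is a true negative when the
  system assigned nothing and a false negative when it assigned something
  (the convention treats the human extractability judgement as the
  condition and the system's assignment as the test outcome);

* signal quality — general PPV (validated events over *all* alerts,
  evaluated or not), specific PPV (events over manually evaluated signals
  only), inter-rater agreement between two detection arms used as a
  relative sensitivity when no gold standard of all true events exists,
  Wald confidence intervals, event deduplication, validation-time
  timeliness, and the one-sided Wilcoxon signed-rank test.

Metric values are percentages in [0, 100]; an undefined metric (zero
denominator) is NaN, never a division error.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, model_validator
from scipy import stats

from .geo import GeoMatch

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "GeoAnnotation",
    "AlertTriage",
    "UniqueEvent",
    "confusion_metrics",
    "geolocation_accuracy",
    "ppv_specific",
    "ppv_general",
    "ira",
    "wald_ci",
    "dedup_events",
    "paired_time_diffs",
    "timeliness",
    "wilcoxon_signed_rank",
    "display_round",
]

UNDEFINED = float("nan")

AUTOMATED = "automated"
MANUAL = "manual"


def display_round(x: float, ndigits: int = 1) -> float:
    """Half-up rounding for presentation (so 76.15 prints as 76.2)."""
    x = float(x)
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Fractional counts are allowed: metrics are averaged over raters."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence: float


def _ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else UNDEFINED


def confusion_metrics(c: ConfusionCounts, accuracy: float = UNDEFINED) -> MetricSet:
    """Standard confusion-matrix metrics on the percentage scale.

    NPV is tn/(tn+fn).  ``accuracy`` is the per-tweet location-match
    accuracy, which is defined against the annotation, not the confusion
    matrix; pass it through when known.
    """
    return MetricSet(
        accuracy=accuracy,
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        prevalence=_ratio(c.tp + c.fn, c.total),
    )


@dataclass(frozen=True)
class GeoAnnotation:
    """One rater's judgement of one tweet plus the system's prediction."""

    tweet_id: str
    rater: str
    gold_country: Optional[str] = None
    gold_admin1: Optional[str] = None
    predicted: Optional[GeoMatch] = None


Level = Literal["national", "subnational"]


def _gold_at(a: GeoAnnotation, level: Level):
    if level == "national":
        return a.gold_country or None
    if a.gold_country and a.gold_admin1:
        return (a.gold_country, a.gold_admin1)
    return None


def _pred_at(a: GeoAnnotation, level: Level):
    p = a.predicted
    if p is None:
        return None
    if level == "national":
        return p.country or None
    if p.country and p.admin1:
        return (p.country, p.admin1)
    return None


def geolocation_accuracy(
    annotations: Sequence[GeoAnnotation], level: Level = "national"
) -> tuple[float, ConfusionCounts, MetricSet]:
    """Accuracy and extractability confusion metrics at one level.

    Per (tweet, rater): the accuracy indicator is 1 when the predicted and
    gold locations both exist and agree at ``level``.  Indicators and
    confusion counts are averaged across raters, so a tweet judged by two
    disagreeing raters contributes fractionally.
    """
    if level not in ("national", "subnational"):
        raise ValueError(f"unknown level: {level!r}")
    seen: set[tuple[str, str]] = set()
    per_rater: dict[str, dict[str, float]] = {}
    match_by_tweet: dict[str, list[float]] = {}
    for a in annotations:
        key = (a.tweet_id, a.rater)
        if key in seen:
            raise ValueError(f"duplicate annotation for tweet {a.tweet_id} by rater {a.rater}")
        seen.add(key)
        gold = _gold_at(a, level)
        pred = _pred_at(a, level)
        cell = per_rater.setdefault(a.rater, {"tp": 0.0, "fp": 0.0, "tn": 0.0, "fn": 0.0})
        if gold is not None:  # positive hit: rater could extract a location
            cell["tp" if pred is not None else "fp"] += 1
        else:  # negative hit
            cell["tn" if pred is None else "fn"] += 1
        match_by_tweet.setdefault(a.tweet_id, []).append(
            1.0 if (gold is not None and pred is not None and gold == pred) else 0.0
        )
    if not per_rater:
        raise ValueError("no annotations")
    n_raters = len(per_rater)
    avg = {
        k: sum(cell[k] for cell in per_rater.values()) / n_raters for k in ("tp", "fp", "tn", "fn")
    }
    counts = ConfusionCounts(**avg)
    matches = sum(np.mean(v) for v in match_by_tweet.values())
    accuracy = 100.0 * matches / len(match_by_tweet)
    return accuracy, counts, confusion_metrics(counts, accuracy=accuracy)


# ---------------------------------------------------------------------------
# Signal-detection evaluation


def ppv_specific(n_events: float, n_false_signals: float) -> float:
    """Events over manually evaluated signals, as a percentage."""
    return _ratio(n_events, n_events + n_false_signals)


def ppv_general(n_events: float, n_false_signals: float, n_not_evaluated: float) -> float:
    """Events over all alerts (evaluated signals plus unevaluated alerts)."""
    return _ratio(n_events, n_events + n_false_signals + n_not_evaluated)


def ira(n_detected_by_method: float, n_total_evaluated: float) -> float:
    """Inter-rater agreement: share of all evaluated signals a method found."""
    if n_total_evaluated <= 0:
        return UNDEFINED
    if not 0 <= n_detected_by_method <= n_total_evaluated:
        raise ValueError("detected count must lie in [0, total]")
    return 100.0 * n_detected_by_method / n_total_evaluated


def wald_ci(successes: float, n: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation binomial CI on the percentage scale, clipped to [0, 100]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    p = successes / n
    z = stats.norm.ppf((1 + level) / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    return 100.0 * max(0.0, p - half), 100.0 * min(1.0, p + half)


# ---------------------------------------------------------------------------
# Unique events, timeliness, Wilcoxon


class AlertTriage(BaseModel):
    """Outcome of the manual triage of one alert."""

    alert_id: str
    status: Literal["not_evaluated", "false_signal", "event"]
    detected_by: frozenset[str] = frozenset()
    validation_time: Optional[dt.datetime] = None
    topic: str = ""
    subtopic: str = ""

    @model_validator(mode="after")
    def _check(self) -> "AlertTriage":
        if (self.status == "event") != (self.validation_time is not None):
            raise ValueError("validation_time present iff status is 'event'")
        bad = self.detected_by - {AUTOMATED, MANUAL}
        if bad:
            raise ValueError(f"unknown detection methods: {sorted(bad)}")
        return self


@dataclass(frozen=True)
class UniqueEvent:
    """Events deduplicated by (topic, subtopic); earliest validation per arm."""

    topic: str
    subtopic: str
    validation_times: dict[str, dt.datetime] = field(default_factory=dict)


def dedup_events(triaged: Sequence[AlertTriage]) -> list[UniqueEvent]:
    """Group validated events by (topic, subtopic); the same threat caught on
    different days or in different regions collapses to one unique event."""
    groups: dict[tuple[str, str], dict[str, dt.datetime]] = {}
    order: list[tuple[str, str]] = []
    for t in triaged:
        if t.status != "event":
            continue
        if not t.subtopic:
            raise ValueError(f"event {t.alert_id} lacks a subtopic")
        key = (t.topic, t.subtopic)
        if key not in groups:
            groups[key] = {}
            order.append(key)
        times = groups[key]
        for method in t.detected_by:
            assert t.validation_time is not None
            if method not in times or t.validation_time < times[method]:
                times[method] = t.validation_time
    return [UniqueEvent(topic=k[0], subtopic=k[1], validation_times=groups[k]) for k in order]


def paired_time_diffs(events: Sequence[UniqueEvent]) -> list[float]:
    """Automated-minus-manual validation-time differences in hours, for
    unique events both arms detected; negative means the automated arm was
    earlier."""
    diffs = []
    for e in events:
        if AUTOMATED in e.validation_times and MANUAL in e.validation_times:
            delta = e.validation_times[AUTOMATED] - e.validation_times[MANUAL]
            diffs.append(delta.total_seconds() / 3600.0)
    return diffs


def timeliness(paired_diffs: Sequence[float]) -> tuple[float, float, float]:
    """(median, q1, q3) of paired differences, linear interpolation."""
    d = np.asarray(paired_diffs, dtype=float)
    if d.size == 0:
        raise ValueError("no paired differences")
    q1, med, q3 = np.percentile(d, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def _signed_rank_pmf(ranks: Sequence[float]) -> dict[float, float]:
    """Exact null pmf of W+ over all sign assignments of the given ranks."""
    dist: dict[float, float] = {0.0: 1.0}
    for r in ranks:
        nxt: dict[float, float] = {}
        for w, p in dist.items():
            nxt[w] = nxt.get(w, 0.0) + p / 2
            nxt[w + r] = nxt.get(w + r, 0.0) + p / 2
        dist = nxt
    return dist


def wilcoxon_signed_rank(
    diffs: Sequence[float], alternative: Literal["less", "greater"] = "less"
) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test; returns (W+, p).

    Zero differences are dropped.  The null distribution is exact (by
    enumeration over sign assignments) for n <= 15 without ties in |d|;
    otherwise the normal approximation with tie and continuity corrections
    is used.  ``alternative="less"`` tests for systematically negative
    differences (small W+).
    """
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(absd)) < n
    if n <= 15 and not has_ties:
        pmf = _signed_rank_pmf(list(ranks))
        if alternative == "less":
            p = sum(prob for w, prob in pmf.items() if w <= w_plus + 1e-9)
        else:
            p = sum(prob for w, prob in pmf.items() if w >= w_plus - 1e-9)
        return w_plus, float(min(p, 1.0))
    mean = n * (n + 1) / 4
    var = n * (n + 1) * (2 * n + 1) / 24
    _, tie_counts = np.unique(absd, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48
    sd = math.sqrt(var)
    if alternative == "less":
        z = (w_plus - mean + 0.5) / sd
        p = stats.norm.cdf(z)
    else:
        z = (w_plus - mean - 0.5) / sd
        p = stats.norm.sf(z)
    return w_plus, float(p)
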