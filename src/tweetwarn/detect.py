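"""Modified-EARS aberration detection with Farrington-style downweighting.

For each topic×region series the detector takes the ``baseline_days`` daily
counts of original posts immediately preceding the evaluation date (default
7; optionally the same weekdays only), optionally downweights baseline
values that look like past spikes, and raises a signal when the current
day's count strictly exceeds the upper bound of a one-sided prediction
interval:

    threshold = mu_w + t_{1-alpha, N-1} * sd_w * sqrt(1 + 1/N)

where ``mu_w`` and ``sd_w`` are the weighted baseline mean and standard
deviation (frequency-weight convention) and ``alpha`` is the nominal
false-positive rate — the alert confidence is ``1 - alpha``.

Downweighting keeps historical outbreaks from inflating the threshold and
masking a new one: baseline values whose standardised residual exceeds a
strength-dependent cut ``c`` (3 / 2 / 1.5 for low / medium / high) get
weight ``(c/r)^2``; only high-side outliers are flagged, since low values
never mask a rise.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy import stats

from .aggregate import CountSeries, WordCount, top_words
from .stream import TweetRecord

__all__ = [
    "SignalConfig",
    "Signal",
    "Alert",
    "downweight_baseline",
    "ears_threshold",
    "detect_signals",
    "build_alert",
]

_STRENGTH_CUT = {"low": 3.0, "medium": 2.0, "high": 1.5}

Strength = Literal["none", "low", "medium", "high"]


class SignalConfig(BaseModel):
    """Detection parameters; snapshotted onto every signal and alert."""

    alpha: float = Field(default=0.025, gt=0, lt=1)
    baseline_days: int = Field(default=7, ge=2)
    downweight_strength: Strength = "none"
    same_weekday_only: bool = False
    include_retweets: bool = False  # count_total instead of count_original
    top_word_k: int = Field(default=20, ge=1)


@dataclass(frozen=True)
class Signal:
    topic: str
    region: str
    date: dt.date
    hour: int
    observed: int
    expected: float
    threshold: float
    config: SignalConfig

    def __post_init__(self) -> None:
        if not self.observed > self.threshold:
            raise ValueError("a signal requires observed > threshold")
        if self.expected > self.threshold + 1e-12:
            raise ValueError("expected must not exceed threshold")


@dataclass(frozen=True)
class Alert:
    date: dt.date
    hour: int
    topic: str
    region: str
    top_words: tuple[WordCount, ...]
    tweet_count: int
    trusted_pct: float
    config: SignalConfig


def downweight_baseline(values: Sequence[float], strength: Strength = "none") -> np.ndarray:
    """Per-value weights in (0, 1]; past high outliers get ``(c/r)^2``.

    Residuals are standardised against the unweighted baseline mean and sd;
    a flat baseline (sd 0) downweights nothing.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 baseline values")
    if strength not in ("none", "low", "medium", "high"):
        raise ValueError(f"unknown strength: {strength!r}")
    weights = np.ones_like(y)
    if strength == "none":
        return weights
    mu = y.mean()
    sd = y.std(ddof=1)
    if sd == 0:
        return weights
    c = _STRENGTH_CUT[strength]
    r = (y - mu) / sd
    flagged = r > c
    weights[flagged] = (c / r[flagged]) ** 2
    return weights


def ears_threshold(
    values: Sequence[float], weights: Sequence[float] | None = None, alpha: float = 0.025
) -> tuple[float, float]:
    """Weighted baseline mean and one-sided prediction-interval bound.

    Returns ``(expected, threshold)`` with ``threshold >= expected``.  The
    weighted sd uses the frequency-weight convention (denominator
    ``sum(w) - 1``, taken as 0 when ``sum(w) <= 1``).
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 baseline values")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != y.shape:
        raise ValueError("weights must align with values")
    wsum = w.sum()
    mu = float(np.sum(w * y) / wsum)
    if wsum > 1:
        var = float(np.sum(w * (y - mu) ** 2) / (wsum - 1))
    else:
        var = 0.0
    sd = np.sqrt(var)
    t = stats.t.ppf(1 - alpha, n - 1)
    threshold = mu + t * sd * np.sqrt(1 + 1 / n)
    return mu, float(max(threshold, mu))


def _baseline_dates(
    available: Sequence[dt.date], as_of_date: dt.date, config: SignalConfig
) -> list[dt.date]:
    past = [d for d in available if d < as_of_date]
    if config.same_weekday_only:
        past = [d for d in past if d.weekday() == as_of_date.weekday()]
    if len(past) < config.baseline_days:
        kind = "same-weekday " if config.same_weekday_only else ""
        raise ValueError(
            f"insufficient history: need {config.baseline_days} {kind}days before {as_of_date}, "
            f"have {len(past)}"
        )
    return sorted(past)[-config.baseline_days :]


def detect_signals(
    series: CountSeries, config: SignalConfig, as_of: dt.datetime
) -> list[Signal]:
    """Evaluate one series at ``as_of``; at most one signal is emitted.

    The baseline is the ``baseline_days`` days immediately preceding the
    evaluation date; the evaluation day's own count (as accumulated so far)
    is the observation.  A signal requires ``observed > threshold`` strictly.
    """
    as_of_date = as_of.date() if isinstance(as_of, dt.datetime) else as_of
    hour = as_of.hour if isinstance(as_of, dt.datetime) else 0
    column = "count_total" if config.include_retweets else "count_original"
    counts = series.counts[column]
    base_dates = _baseline_dates(list(counts.index), as_of_date, config)
    baseline = counts.loc[base_dates].to_numpy(dtype=float)
    observed = int(counts.loc[as_of_date]) if as_of_date in counts.index else 0
    weights = downweight_baseline(baseline, config.downweight_strength)
    expected, threshold = ears_threshold(baseline, weights, config.alpha)
    if observed > threshold:
        return [
            Signal(
                topic=series.topic,
                region=series.region,
                date=as_of_date,
                hour=hour,
                observed=observed,
                expected=expected,
                threshold=threshold,
                config=config,
            )
        ]
    return []


def build_alert(
    signal: Signal,
    records: Sequence[TweetRecord],
    stop_lists=None,
) -> Alert:
    """Assemble the alert record for a signal from its day's original posts.

    ``records`` must be exactly the original (non-retweet, non-quote) posts
    counted in ``signal.observed``; the trusted percentage is computed over
    them.
    """
    originals = [r for r in records if not (r.is_retweet or r.is_quote)]
    if len(originals) != signal.observed:
        raise ValueError(
            f"record set inconsistent with signal: {len(originals)} originals "
            f"vs observed {signal.observed}"
        )
    trusted = sum(1 for r in originals if r.trusted)
    trusted_pct = 100.0 * trusted / len(originals) if originals else 0.0
    words = top_words(originals, k=signal.config.top_word_k, stop_lists=stop_lists)
    return Alert(
        date=signal.date,
        hour=signal.hour,
        topic=signal.topic,
        region=signal.region,
        top_words=tuple(words),
        tweet_count=signal.observed,
        trusted_pct=trusted_pct,
        config=signal.config,
    )
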