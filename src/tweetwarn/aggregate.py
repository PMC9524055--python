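"""Aggregation of geolocated records into topic×region daily count series.

Each record is counted once at national level under its *resolved* country —
the tweet-text location when one was accepted, else the user location — and
propagated upward to that country's continent, to the "AMERICA" super-region
for countries of the Americas, and to "WORLD".  Records with no accepted
location at all still count at world level, so the world series conserves
the stream total.  Retweets and quoted posts are excluded from
``count_original`` (the series signal detection runs on) but kept in
``count_total``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._text import tokens
from .geo import GeoMatch
from .stream import TweetRecord

__all__ = [
    "LocatedTweet",
    "CountSeries",
    "WordCount",
    "continent_map",
    "regions_for",
    "default_stop_words",
    "aggregate_counts",
    "top_words",
    "series_to_frame",
    "frame_to_series",
]

WORLD = "WORLD"
AMERICA = "AMERICA"
_AMERICAS = {"NA", "SA"}


@dataclass(frozen=True)
class LocatedTweet:
    """A record paired with its (optional) tweet and user geolocations."""

    record: TweetRecord
    tweet_match: Optional[GeoMatch] = None
    user_match: Optional[GeoMatch] = None

    @property
    def resolved_country(self) -> Optional[str]:
        """Tweet-text location first; user location as fallback."""
        if self.tweet_match is not None:
            return self.tweet_match.country
        if self.user_match is not None:
            return self.user_match.country
        return None


@dataclass
class CountSeries:
    """Daily counts for one topic×region cell, zero-filled and contiguous."""

    topic: str
    region: str
    counts: pd.DataFrame  # index: dates; columns: count_original, count_total, trusted_count

    def __post_init__(self) -> None:
        c = self.counts
        bad = ~(
            (c["trusted_count"] <= c["count_original"])
            & (c["count_original"] <= c["count_total"])
            & (c["trusted_count"] >= 0)
        )
        if bad.any():
            raise ValueError(f"count ordering violated for {self.topic}/{self.region}")

    def original(self) -> pd.Series:
        return self.counts["count_original"]


@dataclass(frozen=True)
class WordCount:
    word: str
    n: int


def continent_map() -> dict[str, str]:
    """Bundled ISO-3166-1 alpha-2 country → continent code table."""
    text = resources.files("tweetwarn.data").joinpath("country_continent.csv").read_text()
    out: dict[str, str] = {}
    for line in text.strip().splitlines()[1:]:
        country, continent = line.split(",")
        out[country] = continent
    return out


def regions_for(country: str, cmap: dict[str, str]) -> list[str]:
    """All aggregation regions a located record counts under."""
    if country not in cmap:
        raise ValueError(f"unknown country code: {country}")
    continent = cmap[country]
    regions = [country, continent]
    if continent in _AMERICAS:
        regions.append(AMERICA)
    regions.append(WORLD)
    return regions


def aggregate_counts(
    located: Sequence[LocatedTweet],
    region_map: dict[str, str] | None = None,
) -> dict[tuple[str, str], CountSeries]:
    """Build topic×region daily series from located records.

    Every record contributes exactly once at world level; located records
    additionally count under their country, continent and (for the Americas)
    the AMERICA super-region.  Dates are zero-filled over the full covered
    range of the input so all series are contiguous and aligned.
    """
    cmap = region_map if region_map is not None else continent_map()
    if not located:
        return {}
    dates = [lt.record.date for lt in located]
    full_range = pd.date_range(min(dates), max(dates), freq="D").date
    acc: dict[tuple[str, str], dict[dt.date, list[int]]] = {}

    def bump(topic: str, region: str, day: dt.date, original: bool, trusted: bool) -> None:
        cell = acc.setdefault((topic, region), {})
        row = cell.setdefault(day, [0, 0, 0])  # original, total, trusted
        row[1] += 1
        if original:
            row[0] += 1
            if trusted:
                row[2] += 1

    for lt in located:
        rec = lt.record
        original = not (rec.is_retweet or rec.is_quote)
        country = lt.resolved_country
        regions = regions_for(country, cmap) if country else [WORLD]
        for region in regions:
            bump(rec.topic, region, rec.date, original, rec.trusted)

    out: dict[tuple[str, str], CountSeries] = {}
    for (topic, region), cell in acc.items():
        frame = pd.DataFrame(
            [cell.get(d, [0, 0, 0]) for d in full_range],
            index=pd.Index(full_range, name="date"),
            columns=["count_original", "count_total", "trusted_count"],
        )
        out[(topic, region)] = CountSeries(topic=topic, region=region, counts=frame)
    return out


def default_stop_words(languages: Iterable[str] = ("en", "fr", "pt", "es")) -> set[str]:
    words: set[str] = set()
    for lang in languages:
        text = resources.files("tweetwarn.data").joinpath(f"stopwords_{lang}.txt").read_text()
        words.update(w.casefold() for w in text.split() if w)
    return words


def top_words(
    records: Sequence[TweetRecord] | Sequence[str],
    k: int = 20,
    stop_lists: Iterable[Iterable[str]] | None = None,
) -> list[WordCount]:
    """The ``k`` most frequent non-stop-word tokens; ties break lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    stops: set[str] = set()
    if stop_lists is None:
        stops = default_stop_words()
    else:
        for lst in stop_lists:
            stops.update(w.casefold() for w in lst)
    counts: dict[str, int] = {}
    for item in records:
        text = item if isinstance(item, str) else item.text
        for tok in tokens(text):
            if tok in stops:
                continue
            counts[tok] = counts.get(tok, 0) + 1
    ranked = sorted(counts.items(), key=lambda wn: (-wn[1], wn[0]))
    return [WordCount(word=w, n=n) for w, n in ranked[:k]]


def series_to_frame(series: dict[tuple[str, str], CountSeries]) -> pd.DataFrame:
    """Tidy long-format frame: topic,region,date,count_original,count_total,trusted_count."""
    rows = []
    for (topic, region), cs in sorted(series.items()):
        frame = cs.counts.reset_index()
        frame.insert(0, "topic", topic)
        frame.insert(1, "region", region)
        rows.append(frame)
    if not rows:
        return pd.DataFrame(
            columns=["topic", "region", "date", "count_original", "count_total", "trusted_count"]
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_series(frame: pd.DataFrame) -> dict[tuple[str, str], CountSeries]:
    out: dict[tuple[str, str], CountSeries] = {}
    for (topic, region), grp in frame.groupby(["topic", "region"]):
        counts = grp.set_index(pd.to_datetime(grp["date"]).dt.date)[
            ["count_original", "count_total", "trusted_count"]
        ]
        counts.index.name = "date"
        out[(topic, region)] = CountSeries(topic=topic, region=region, counts=counts)
    return out


def write_series_csv(series: dict[tuple[str, str], CountSeries], path: str | Path) -> Path:
    path = Path(path)
    series_to_frame(series).to_csv(path, index=False)
    return path


def read_series_csv(path: str | Path) -> dict[tuple[str, str], CountSeries]:
    return frame_to_series(pd.read_csv(path))
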