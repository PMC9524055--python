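"""Tweet-record data model, JSON Lines I/O and a synthetic stream generator.

The generator stands in for a live social-media collection API: it emits
tweet-like records whose daily volume per topic and country follows a
negative-binomial count model (overdispersed, as real tweet streams are; the
dispersion ``k`` recovers a Poisson stream as ``k → ∞``), with configurable
retweet/quote/trusted fractions and templated texts that embed gazetteer place
names verbatim so geolocation ground truth is known for every record.
Multi-day outbreak bursts are injected as multiplicative rate factors,
providing ground truth for detection-power experiments.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "TweetRecord",
    "TopicRates",
    "StreamSpec",
    "OutbreakSpec",
    "read_tweets",
    "write_tweets",
    "generate_stream",
    "generate_stream_with_truth",
]

_JSONL_KEYS = (
    "tweet_id",
    "created_at",
    "topic",
    "text",
    "lang",
    "is_retweet",
    "is_quote",
    "origin_text",
    "user_geo",
    "user_declared",
    "user_profile",
    "trusted",
)
_REQUIRED_KEYS = (
    "tweet_id",
    "created_at",
    "topic",
    "text",
    "lang",
    "is_retweet",
    "is_quote",
    "trusted",
)


class TweetRecord(BaseModel):
    """One post: text, timestamps, retweet/quote flags and user locations.

    ``user_geo`` is the user's location at the time of the post, ``user_declared``
    the self-declared location, ``user_profile`` the location in the public
    profile/biography; user-location resolution tries them in that order.
    """

    model_config = ConfigDict(frozen=True)

    tweet_id: str
    created_at: dt.datetime
    topic: str
    text: str
    lang: str
    is_retweet: bool = False
    is_quote: bool = False
    origin_text: Optional[str] = None
    user_geo: Optional[str] = None
    user_declared: Optional[str] = None
    user_profile: Optional[str] = None
    trusted: bool = False

    @field_validator("created_at")
    @classmethod
    def _utc(cls, v: dt.datetime) -> dt.datetime:
        if v.tzinfo is None:
            raise ValueError("created_at must be timezone-aware")
        return v.astimezone(dt.timezone.utc)

    @model_validator(mode="after")
    def _flags(self) -> "TweetRecord":
        if self.is_retweet and self.is_quote:
            raise ValueError("is_retweet and is_quote cannot both be true")
        if self.origin_text is not None and not (self.is_retweet or self.is_quote):
            raise ValueError("origin_text only valid for retweets/quotes")
        return self

    @property
    def date(self) -> dt.date:
        return self.created_at.date()


class TopicRates(BaseModel):
    """A monitored topic with baseline daily posting rates per country."""

    name: str
    rates: dict[str, float]  # ISO-3166-1 alpha-2 country -> posts/day

    @field_validator("rates")
    @classmethod
    def _nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        for c, lam in v.items():
            if not math.isfinite(lam) or lam < 0:
                raise ValueError(f"rate for {c} must be finite and >= 0")
        return v


class StreamSpec(BaseModel):
    """Conditions of a synthetic collection run."""

    topics: list[TopicRates]
    dispersion: float = Field(default=math.inf, gt=0)
    retweet_frac: float = Field(default=0.3, ge=0, le=1)
    quote_frac: float = Field(default=0.1, ge=0, le=1)
    trusted_frac: float = Field(default=0.05, ge=0, le=1)
    place_mention_prob: float = Field(default=0.6, ge=0, le=1)
    user_location_prob: float = Field(default=0.5, ge=0, le=1)
    start_date: dt.date
    end_date: dt.date
    languages: tuple[str, ...] = ("en", "fr", "pt", "es")
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "StreamSpec":
        if self.retweet_frac + self.quote_frac > 1:
            raise ValueError("retweet_frac + quote_frac must be <= 1")
        if self.end_date < self.start_date:
            raise ValueError("end_date before start_date")
        return self


class OutbreakSpec(BaseModel):
    """Ground-truth burst: rate multiplied by ``magnitude`` inside the window."""

    topic: str
    region: str  # country code
    start: dt.date
    end: dt.date
    magnitude: float = Field(gt=1)

    @model_validator(mode="after")
    def _check(self) -> "OutbreakSpec":
        if self.end < self.start:
            raise ValueError("outbreak end before start")
        return self


# ---------------------------------------------------------------------------
# JSON Lines I/O


def read_tweets(path: str | Path) -> list[TweetRecord]:
    """Read line-delimited tweet records (one JSON object per line, UTF-8).

    Unknown keys are ignored; timestamps are normalised to UTC. Raises
    ``ValueError`` naming the line number for malformed lines and the missing
    key for incomplete records.
    """
    records: list[TweetRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"malformed JSON on line {lineno}: {exc}") from exc
            if not isinstance(obj, dict):
                raise ValueError(f"malformed record on line {lineno}: not an object")
            for key in _REQUIRED_KEYS:
                if key not in obj:
                    raise ValueError(f"line {lineno}: missing required key '{key}'")
            try:
                created = dt.datetime.fromisoformat(str(obj["created_at"]))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: bad created_at: {exc}") from exc
            fields = {k: obj.get(k) for k in _JSONL_KEYS if k in obj}
            fields["created_at"] = created
            try:
                records.append(TweetRecord(**fields))
            except Exception as exc:
                raise ValueError(f"line {lineno}: invalid record: {exc}") from exc
    return records


def write_tweets(records: Iterable[TweetRecord], path: str | Path) -> Path:
    """Write records as JSON Lines; ``read_tweets`` round-trips the output."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = {k: getattr(rec, k) for k in _JSONL_KEYS}
            obj["created_at"] = rec.created_at.isoformat()
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    return path


# ---------------------------------------------------------------------------
# Synthetic generation

# Template pools per language. {p} is replaced by a gazetteer place name
# verbatim so downstream geolocation can recover it.
_PLACE_TEMPLATES = {
    "en": ["{t} outbreak reported in {p}", "new {t} cases in {p}", "{t} alert in {p} today"],
    "fr": ["épidémie de {t} signalée à {p}", "nouveaux cas de {t} à {p}", "alerte {t} à {p}"],
    "pt": ["surto de {t} relatado em {p}", "novos casos de {t} em {p}", "alerta de {t} em {p}"],
    "es": ["brote de {t} reportado en {p}", "nuevos casos de {t} en {p}", "alerta de {t} en {p}"],
}
_NOPLACE_TEMPLATES = {
    "en": ["{t} situation update", "more {t} cases reported", "monitoring the {t} news"],
    "fr": ["point de situation {t}", "plus de cas de {t} signalés", "suivi de {t}"],
    "pt": ["atualização sobre {t}", "mais casos de {t} relatados", "acompanhando {t}"],
    "es": ["actualización sobre {t}", "más casos de {t} reportados", "siguiendo {t}"],
}


def _days(spec: StreamSpec) -> list[dt.date]:
    n = (spec.end_date - spec.start_date).days + 1
    return [spec.start_date + dt.timedelta(days=i) for i in range(n)]


def _draw_count(rng: np.random.Generator, mean: float, k: float) -> int:
    if mean <= 0:
        return 0
    if math.isinf(k):
        return int(rng.poisson(mean))
    return int(rng.negative_binomial(k, k / (k + mean)))


def generate_stream_with_truth(
    spec: StreamSpec,
    gazetteer: Sequence | None = None,
    outbreaks: Sequence[OutbreakSpec] | None = None,
) -> tuple[list[TweetRecord], dict[str, Optional[str]]]:
    """Generate a seeded synthetic stream plus per-record ground truth.

    Returns ``(records, truth)`` where ``truth[tweet_id]`` is the ISO country
    code of the place embedded in the record's text (or origin text), or None
    when no place was embedded. Deterministic given ``spec.seed``.
    """
    outbreaks = list(outbreaks or [])
    for ob in outbreaks:
        if ob.start < spec.start_date or ob.end > spec.end_date:
            raise ValueError("outbreak window outside stream date range")
    places: list = list(gazetteer) if gazetteer is not None else []
    if spec.place_mention_prob > 0 and not places:
        raise ValueError("non-empty gazetteer required when place_mention_prob > 0")

    rng = np.random.default_rng(spec.seed)
    records: list[TweetRecord] = []
    truth: dict[str, Optional[str]] = {}
    counter = 0
    days = _days(spec)
    for topic in spec.topics:
        for country in sorted(topic.rates):
            lam = topic.rates[country]
            for day in days:
                mag = 1.0
                for ob in outbreaks:
                    if ob.topic == topic.name and ob.region == country and ob.start <= day <= ob.end:
                        mag *= ob.magnitude
                n = _draw_count(rng, lam * mag, spec.dispersion)
                for _ in range(n):
                    counter += 1
                    rec, country_truth = _make_record(
                        rng, spec, places, topic.name, day, f"t{counter:09d}"
                    )
                    records.append(rec)
                    truth[rec.tweet_id] = country_truth
    return records, truth


def _pick_place(rng: np.random.Generator, places: list):
    entry = places[int(rng.integers(len(places)))]
    return entry


def _make_record(
    rng: np.random.Generator,
    spec: StreamSpec,
    places: list,
    topic: str,
    day: dt.date,
    tweet_id: str,
) -> tuple[TweetRecord, Optional[str]]:
    lang = spec.languages[int(rng.integers(len(spec.languages)))]
    second = int(rng.integers(86400))
    created = dt.datetime.combine(day, dt.time(0), dt.timezone.utc) + dt.timedelta(seconds=second)

    mention = bool(rng.random() < spec.place_mention_prob)
    if mention:
        entry = _pick_place(rng, places)
        tpl = _PLACE_TEMPLATES[lang][int(rng.integers(len(_PLACE_TEMPLATES[lang])))]
        body = tpl.format(t=topic, p=entry.name)
        country_truth: Optional[str] = entry.country
    else:
        tpl = _NOPLACE_TEMPLATES[lang][int(rng.integers(len(_NOPLACE_TEMPLATES[lang])))]
        body = tpl.format(t=topic)
        country_truth = None

    u = rng.random()
    is_retweet = u < spec.retweet_frac
    is_quote = (not is_retweet) and u < spec.retweet_frac + spec.quote_frac
    if is_retweet or is_quote:
        # the share-style post itself carries no place; the shared text does
        own_tpl = _NOPLACE_TEMPLATES[lang][int(rng.integers(len(_NOPLACE_TEMPLATES[lang])))]
        text, origin_text = own_tpl.format(t=topic), body
    else:
        text, origin_text = body, None

    user_geo = user_declared = user_profile = None
    if places and rng.random() < spec.user_location_prob:
        loc = _pick_place(rng, places).name
        slot = int(rng.integers(3))
        if slot == 0:
            user_geo = loc
        elif slot == 1:
            user_declared = loc
        else:
            user_profile = loc

    rec = TweetRecord(
        tweet_id=tweet_id,
        created_at=created,
        topic=topic,
        text=text,
        lang=lang,
        is_retweet=is_retweet,
        is_quote=is_quote,
        origin_text=origin_text,
        user_geo=user_geo,
        user_declared=user_declared,
        user_profile=user_profile,
        trusted=bool(rng.random() < spec.trusted_frac),
    )
    return rec, country_truth


def generate_stream(
    spec: StreamSpec,
    gazetteer: Sequence | None = None,
    outbreaks: Sequence[OutbreakSpec] | None = None,
) -> list[TweetRecord]:
    """Seeded synthetic tweet stream (see :func:`generate_stream_with_truth`)."""
    records, _ = generate_stream_with_truth(spec, gazetteer, outbreaks)
    return records
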