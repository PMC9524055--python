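"""Two-step tweet geolocation against a GeoNames-style gazetteer.

Step 1 finds location *candidates*: each token of the text is scored by a
trainable word classifier (location vs common word) and maximal runs of
high-scoring consecutive tokens become candidate spans, so multiword places
("Ciudad Real") stay together.  Step 2 matches each candidate against a
tf-idf-weighted gazetteer index with a vector-space-style score; the best
match above a user threshold (default 10) becomes the geolocation.

The score of a candidate against an entry is

    sum(idf(t) * field_boost(t)) * coverage * (1 + population_boost) [* exact_boost]

over the query tokens the entry contains, where *coverage* is the matched
fraction of query tokens and *exact_boost* applies only when the candidate
surface equals the entry's name (or an alternate name) in full.  Coverage is
what keeps a bare common token ("real") from outranking the two-token place
("Ciudad Real") it belongs to, and the exact-name boost is calibrated so a
full, exact match of a populated place lands well above the default
threshold while single-token partial matches land below it.

Tweet location looks at the post's own text first and falls back to the
retweeted/quoted text; user location tries, in priority order, the location
at posting time, the self-declared location, then the profile location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from ._text import tokenize, tokens

__all__ = [
    "GazetteerEntry",
    "GazetteerIndex",
    "CandidateSpan",
    "GeoMatch",
    "ClassifierParams",
    "IndexParams",
    "load_geonames",
    "train_candidate_classifier",
    "extract_candidates",
    "build_index",
    "match_candidate",
    "geolocate_tweet",
    "geolocate_user",
]

TWEET_SOURCES = ("tweet_text", "origin_text")
USER_SOURCES = ("user_geo", "user_declared", "user_profile")


@dataclass(frozen=True)
class GazetteerEntry:
    entry_id: int
    name: str
    alt_names: tuple[str, ...]
    country: str
    admin1: str
    feature: str  # country | admin1 | populated_place | other
    population: int
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gazetteer entry needs a name")
        if self.population < 0:
            raise ValueError("population must be >= 0")
        if not (-90 <= self.lat <= 90 and -180 <= self.lon <= 180):
            raise ValueError("coordinates out of range")


@dataclass(frozen=True)
class CandidateSpan:
    """A location candidate: half-open character span plus classifier confidence."""

    start: int
    end: int
    surface: str
    candidate_score: float


@dataclass(frozen=True)
class GeoMatch:
    entry_id: int
    match_score: float
    source: str
    country: str
    admin1: str  # empty when the match carries no subnational information
    name: str = ""


def _feature_of(fclass: str, fcode: str) -> str:
    if fclass == "A" and fcode.startswith("PCL"):
        return "country"
    if fclass == "A" and fcode == "ADM1":
        return "admin1"
    if fclass == "P":
        return "populated_place"
    return "other"


def load_geonames(path: str | Path) -> list[GazetteerEntry]:
    """Parse a GeoNames main-dump file (tab-delimited, 19 columns).

    Columns used: geonameid, name, alternatenames (comma-split), feature
    class/code (mapped to country/admin1/populated_place/other), country
    code, admin1 code, population, latitude, longitude.
    """
    entries: list[GazetteerEntry] = []
    with open(path, encoding="utf-8") as fh:
        for rowno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 19:
                raise ValueError(f"row {rowno}: expected 19 columns, got {len(cols)}")
            alt = tuple(a for a in cols[3].split(",") if a)
            entries.append(
                GazetteerEntry(
                    entry_id=int(cols[0]),
                    name=cols[1],
                    alt_names=alt,
                    country=cols[8],
                    admin1=cols[10],
                    feature=_feature_of(cols[6], cols[7]),
                    population=int(cols[14] or 0),
                    lat=float(cols[4]),
                    lon=float(cols[5]),
                )
            )
    return entries


# ---------------------------------------------------------------------------
# Step 1: candidate classifier


class ClassifierParams(BaseModel):
    ngram_min: int = 2
    ngram_max: int = 4
    C: float = Field(default=1.0, gt=0)
    max_iter: int = 300
    seed: int = 0


class CandidateClassifier:
    """Character-n-gram logistic scorer: token -> P(location word) in [0, 1].

    Any object with a compatible ``score_many`` can be plugged in instead; a
    pretrained multilingual embedding model would slot into the same
    interface.
    """

    def __init__(self, vectorizer: CountVectorizer, model: LogisticRegression):
        self._vec = vectorizer
        self._model = model

    def score_many(self, toks: Sequence[str]) -> np.ndarray:
        if len(toks) == 0:
            return np.empty(0)
        X = self._vec.transform([t.casefold() for t in toks])
        return self._model.predict_proba(X)[:, 1]

    def score(self, token: str) -> float:
        return float(self.score_many([token])[0])


def train_candidate_classifier(
    location_words: Sequence[str],
    common_words: Sequence[str],
    params: ClassifierParams | None = None,
) -> CandidateClassifier:
    """Train the location-word scorer on positive/negative word lists.

    The two classes must be non-empty and disjoint after casefolding (the
    usual preparation removes gazetteer names from the common-word list).
    """
    params = params or ClassifierParams()
    pos = sorted({w.casefold() for w in location_words if w.strip()})
    neg = sorted({w.casefold() for w in common_words if w.strip()})
    if not pos or not neg:
        raise ValueError("both training classes must be non-empty")
    overlap = set(pos) & set(neg)
    if overlap:
        raise ValueError(f"training classes overlap after casefolding: {sorted(overlap)[:5]}")
    vec = CountVectorizer(
        analyzer="char_wb", ngram_range=(params.ngram_min, params.ngram_max), lowercase=False
    )
    X = vec.fit_transform(pos + neg)
    y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
    model = LogisticRegression(C=params.C, max_iter=params.max_iter, random_state=params.seed)
    model.fit(X, y)
    return CandidateClassifier(vec, model)


def extract_candidates(
    text: str, classifier: CandidateClassifier, min_candidate_score: float = 0.5
) -> list[CandidateSpan]:
    """Maximal runs of consecutive tokens scoring >= ``min_candidate_score``.

    Spans are returned sorted by descending candidate score (the mean token
    score of the run), so the strongest candidate is tried first downstream.
    """
    toks = tokenize(text or "")
    if not toks:
        return []
    scores = classifier.score_many([t.text for t in toks])
    spans: list[CandidateSpan] = []
    i = 0
    while i < len(toks):
        if scores[i] >= min_candidate_score:
            j = i
            while j + 1 < len(toks) and scores[j + 1] >= min_candidate_score:
                j += 1
            start, end = toks[i].start, toks[j].end
            spans.append(
                CandidateSpan(
                    start=start,
                    end=end,
                    surface=text[start:end],
                    candidate_score=float(np.mean(scores[i : j + 1])),
                )
            )
            i = j + 1
        else:
            i += 1
    spans.sort(key=lambda s: (-s.candidate_score, s.start))
    return spans


# ---------------------------------------------------------------------------
# Step 2: gazetteer index and vector-space matching


class IndexParams(BaseModel):
    """Score-calibration constants (see module docstring for the formula)."""

    name_token_boost: float = 1.0
    alt_token_boost: float = 0.7
    exact_name_boost: float = 3.0
    population_scale: float = 0.05  # boost = scale * log10(1 + population)


@dataclass
class GazetteerIndex:
    entries: list[GazetteerEntry]
    params: IndexParams
    idf: dict[str, float] = field(default_factory=dict)
    postings: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    exact_names: dict[str, list[int]] = field(default_factory=dict)


def build_index(entries: Sequence[GazetteerEntry], params: IndexParams | None = None) -> GazetteerIndex:
    """Build the token->entry postings with idf weights and field boosts."""
    entries = list(entries)
    if not entries:
        raise ValueError("cannot index an empty gazetteer")
    params = params or IndexParams()
    # document frequency over each entry's name + alt-name token set
    entry_tokens: list[dict[str, float]] = []
    df: dict[str, int] = {}
    exact_names: dict[str, list[int]] = {}
    for i, e in enumerate(entries):
        boosts: dict[str, float] = {}
        for t in tokens(e.name):
            boosts[t] = params.name_token_boost
        for alt in e.alt_names:
            for t in tokens(alt):
                boosts.setdefault(t, params.alt_token_boost)
        entry_tokens.append(boosts)
        for t in boosts:
            df[t] = df.get(t, 0) + 1
        for nm in (e.name, *e.alt_names):
            exact_names.setdefault(" ".join(tokens(nm)), []).append(i)
    n = len(entries)
    idf = {t: 1.0 + math.log(n / d) for t, d in df.items()}
    postings: dict[str, list[tuple[int, float]]] = {}
    for i, boosts in enumerate(entry_tokens):
        for t, b in boosts.items():
            postings.setdefault(t, []).append((i, b))
    return GazetteerIndex(entries=entries, params=params, idf=idf, postings=postings, exact_names=exact_names)


def match_candidate(span: CandidateSpan | str, index: GazetteerIndex, top_k: int = 5) -> list[GeoMatch]:
    """Score a candidate against the gazetteer; best matches first.

    Ties break deterministically by higher population, then lower entry id.
    Returns an empty list when no entry shares a token with the candidate.
    """
    surface = span if isinstance(span, str) else span.surface
    qtokens = tokens(surface)
    if not qtokens:
        return []
    qset = list(dict.fromkeys(qtokens))  # unique, order kept
    p = index.params
    acc: dict[int, float] = {}
    for t in qset:
        for i, boost in index.postings.get(t, ()):
            acc[i] = acc.get(i, 0.0) + index.idf[t] * boost
    if not acc:
        return []
    qkey = " ".join(qtokens)
    exact = set(index.exact_names.get(qkey, ()))
    scored: list[tuple[float, int]] = []
    for i, base in acc.items():
        e = index.entries[i]
        etoks = set()
        for nm in (e.name, *e.alt_names):
            etoks.update(tokens(nm))
        coverage = sum(1 for t in qset if t in etoks) / len(qset)
        score = base * coverage * (1.0 + p.population_scale * math.log10(1 + e.population))
        if i in exact:
            score *= p.exact_name_boost
        scored.append((score, i))
    scored.sort(key=lambda si: (-si[0], -index.entries[si[1]].population, index.entries[si[1]].entry_id))
    out = []
    for score, i in scored[:top_k]:
        e = index.entries[i]
        admin1 = e.admin1 if e.feature in ("admin1", "populated_place") else ""
        out.append(
            GeoMatch(
                entry_id=e.entry_id,
                match_score=score,
                source="",
                country=e.country,
                admin1=admin1,
                name=e.name,
            )
        )
    return out


def _best_match_in_text(
    text: Optional[str],
    classifier: CandidateClassifier,
    index: GazetteerIndex,
    min_candidate_score: float,
) -> Optional[GeoMatch]:
    if not text:
        return None
    best: Optional[GeoMatch] = None
    for span in extract_candidates(text, classifier, min_candidate_score):
        matches = match_candidate(span, index, top_k=1)
        if matches and (best is None or matches[0].match_score > best.match_score):
            best = matches[0]
    return best


def geolocate_tweet(
    record,
    classifier: CandidateClassifier,
    index: GazetteerIndex,
    min_score: float = 10.0,
    min_candidate_score: float = 0.5,
) -> Optional[GeoMatch]:
    """Locate the post: own text first, then the retweeted/quoted text.

    A match is accepted only when its score is strictly above ``min_score``.
    """
    for source, text in (("tweet_text", record.text), ("origin_text", record.origin_text)):
        if source == "origin_text" and not (record.is_retweet or record.is_quote):
            break
        best = _best_match_in_text(text, classifier, index, min_candidate_score)
        if best is not None and best.match_score > min_score:
            return GeoMatch(
                entry_id=best.entry_id,
                match_score=best.match_score,
                source=source,
                country=best.country,
                admin1=best.admin1,
                name=best.name,
            )
    return None


def geolocate_user(
    record,
    classifier: CandidateClassifier,
    index: GazetteerIndex,
    min_score: float = 10.0,
    min_candidate_score: float = 0.5,
) -> Optional[GeoMatch]:
    """Locate the author: location at posting time, then self-declared, then profile."""
    for source in USER_SOURCES:
        best = _best_match_in_text(getattr(record, source), classifier, index, min_candidate_score)
        if best is not None and best.match_score > min_score:
            return GeoMatch(
                entry_id=best.entry_id,
                match_score=best.match_score,
                source=source,
                country=best.country,
                admin1=best.admin1,
                name=best.name,
            )
    return None
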