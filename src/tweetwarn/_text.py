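"""Shared tweet-text tokenisation.

One tokeniser is used everywhere (candidate extraction, gazetteer indexing,
top-word summaries) so that scores and counts are computed on the same token
stream: Unicode word characters, casefolded, with URLs and @-mentions removed
and a leading ``#`` stripped from hashtags.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_URL_RE = re.compile(r"https?://\S+|www\.\S+")
_MENTION_RE = re.compile(r"@\w+")
_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


@dataclass(frozen=True)
class Token:
    """A token with its half-open character span in the original text."""

    text: str  # casefolded surface
    start: int
    end: int


def _blank(match: re.Match) -> str:
    return " " * (match.end() - match.start())


def tokenize(text: str) -> list[Token]:
    """Tokenise ``text`` preserving 0-based half-open offsets.

    URLs and @-mentions are blanked out (offsets of the remaining text are
    unchanged); a ``#`` introducing a hashtag is not part of the token.
    """
    if not text:
        return []
    cleaned = _URL_RE.sub(_blank, text)
    cleaned = _MENTION_RE.sub(_blank, cleaned)
    out = []
    for m in _TOKEN_RE.finditer(cleaned):
        tok = m.group(0)
        if tok.replace("_", "") == "":
            continue
        out.append(Token(tok.casefold(), m.start(), m.end()))
    return out


def tokens(text: str) -> list[str]:
    """Casefolded token strings only."""
    return [t.text for t in tokenize(text)]
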