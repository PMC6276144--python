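"""Normalization helpers for Spanish clinical free text.

All lexicon matching in :mod:`certscore.rules` operates on normalized text:
lowercase, accents stripped, whitespace collapsed. Raw (un-normalized) text is
kept only for the all-capitals abbreviation heuristic, which is case-driven.
"""

from __future__ import annotations

import re
import unicodedata

_WS = re.compile(r"\s+")
_WORD = re.compile(r"[a-z0-9]+")


def normalize(text: str) -> str:
    """Lowercase, strip accents and collapse whitespace."""
    text = unicodedata.normalize("NFD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    return _WS.sub(" ", text.lower()).strip()


def tokens(text: str) -> list[str]:
    """Alphanumeric word tokens of the *normalized* text."""
    return _WORD.findall(normalize(text))


def raw_tokens(text: str) -> list[str]:
    """Whitespace/punctuation-delimited tokens of the raw text (case kept)."""
    return re.findall(r"[^\W\d_]+", text, flags=re.UNICODE)


def contains_term(text_norm: str, term: str) -> bool:
    """True if ``term`` occurs in already-normalized text at word boundaries.

    ``term`` may be a multi-word phrase; it is normalized before matching.
    """
    term = normalize(term)
    if not term:
        return False
    return re.search(rf"(?<![a-z0-9]){re.escape(term)}(?![a-z0-9])", text_norm) is not None
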