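"""Text cleansing, tokenization, sentence splitting and lemma/POS providers.

Two tokenization strategies are provided: a plain whitespace tokenizer
(default for word-representation induction) and a "simple" tokenizer that
breaks text into maximal alphanumeric runs or single punctuation marks
(default for the supervised path). Both record exact character offsets into
the source string, so gold annotations in raw coordinates stay valid.

Cleansing (control-character removal plus a fixed special-character
replacement table) is intended for unlabeled text only; it changes string
lengths and therefore must never run on text carrying offset annotations.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Callable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "Sentence",
    "cleanse",
    "tokenize_whitespace",
    "tokenize_simple",
    "split_sentences",
    "lemmatize",
    "default_lemma_provider",
    "REPLACEMENTS",
]


@dataclass
class Token:
    text: str
    start: int
    end: int
    lemma: str = ""
    pos: str | None = None


@dataclass
class Sentence:
    doc_id: str
    section: str
    tokens: list[Token] = field(default_factory=list)
    span: tuple[int, int] = (0, 0)


_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "ο": "omicron",
    "π": "pi", "ρ": "rho", "σ": "sigma", "ς": "sigma", "τ": "tau",
    "υ": "upsilon", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
}

# Fixed, versioned replacement table: Greek letters spelled out, common
# typographic characters folded to ASCII. Everything else passes through.
REPLACEMENTS: dict[str, str] = {
    **_GREEK,
    **{k.upper(): v.capitalize() for k, v in _GREEK.items() if k != "ς"},
    "×": "x",
    "–": "-",
    "—": "-",
    "−": "-",
    "‘": "'",
    "’": "'",
    "“": '"',
    "”": '"',
    " ": " ",
}


def cleanse(text: str) -> str:
    """Remove non-informative control characters and replace special
    characters with ASCII spellings (fixed table).

    Apply only to unlabeled text: replacements change offsets.
    """
    out = []
    for ch in text:
        if ch in REPLACEMENTS:
            out.append(REPLACEMENTS[ch])
        elif ch in ("\n", "\t"):
            out.append(ch)
        elif unicodedata.category(ch) == "Cc":
            continue
        else:
            out.append(ch)
    return "".join(out)


_WS_TOKEN = re.compile(r"\S+")
# a maximal letters-and/or-digits block, or exactly one other visible char
_SIMPLE_TOKEN = re.compile(r"[A-Za-z0-9]+|[^\sA-Za-z0-9]")


def tokenize_whitespace(text: str) -> list[Token]:
    """Split on whitespace: maximal runs of non-whitespace become tokens."""
    return [Token(m.group(), m.start(), m.end()) for m in _WS_TOKEN.finditer(text)]


def tokenize_simple(text: str) -> list[Token]:
    """Break text into contiguous blocks of letters and/or digits or single
    punctuation marks."""
    return [Token(m.group(), m.start(), m.end()) for m in _SIMPLE_TOKEN.finditer(text)]


# Abbreviations that do not end a sentence even when followed by space+capital.
_ABBREVIATIONS = frozenset(
    {
        "e.g.", "i.e.", "cf.", "vs.", "ca.", "al.", "approx.", "fig.", "figs.",
        "eq.", "eqs.", "ref.", "refs.", "no.", "nos.", "vol.", "dr.", "prof.",
        "st.", "mr.", "mrs.", "ms.", "inc.", "etc.",
    }
)

_BOUNDARY = re.compile(r"[.?!]+(?=\s)")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split into sentence spans (0-based, half-open, whitespace-trimmed).

    A split happens after sentence-final punctuation followed by whitespace
    and an uppercase letter or digit, except after known abbreviations and
    never inside an open parenthesis/bracket.
    """
    if not text.strip():
        return []
    cut_points = [0]
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        # next non-space char must start a sentence
        j = end
        while j < len(text) and text[j].isspace():
            j += 1
        if j >= len(text):
            continue
        if not (text[j].isupper() or text[j].isdigit()):
            continue
        # no split inside unmatched parentheses/brackets
        depth = 0
        for ch in text[:end]:
            if ch in "([{":
                depth += 1
            elif ch in ")]}":
                depth = max(0, depth - 1)
        if depth > 0:
            continue
        # the word ending at the punctuation must not be an abbreviation
        k = m.start()
        while k > 0 and not text[k - 1].isspace():
            k -= 1
        word = text[k:end].lower()
        if word in _ABBREVIATIONS:
            continue
        # single uppercase initial like "J." also continues
        if re.fullmatch(r"[A-Z]\.", text[k:end]):
            continue
        cut_points.append(j)
    cut_points.append(len(text))
    spans = []
    for a, b in zip(cut_points[:-1], cut_points[1:]):
        # trim whitespace
        while a < b and text[a].isspace():
            a += 1
        while b > a and text[b - 1].isspace():
            b -= 1
        if a < b:
            spans.append((a, b))
    return spans


_VOWELS = set("aeiou")


def _default_lemma(word: str) -> str:
    """Lowercase and strip a plural 's'/'es' that follows a consonant."""
    lw = word.lower()
    if len(lw) > 3 and lw.endswith("es") and lw[-3].isalpha() and lw[-3] not in _VOWELS:
        return lw[:-2]
    if (
        len(lw) > 2
        and lw.endswith("s")
        and lw[-2].isalpha()
        and lw[-2] not in _VOWELS
        and lw[-2] != "s"  # a plural 's' never follows 's'
    ):
        return lw[:-1]
    return lw


def default_lemma_provider(words: Sequence[str]) -> list[str]:
    """Batch lemma provider: order-preserving, one lemma per input word."""
    return [_default_lemma(w) for w in words]


LemmaProvider = Callable[[Sequence[str]], list[str]]


def lemmatize(tokens: list[Token], provider: LemmaProvider | None = None) -> list[Token]:
    """Fill ``token.lemma`` in place using a batch word->lemma provider.

    On provider failure the affected tokens fall back to their lowercased
    text and a warning is logged. Returns the same token list.
    """
    if provider is None:
        provider = default_lemma_provider
    words = [t.text for t in tokens]
    try:
        lemmas = list(provider(words))
        if len(lemmas) != len(words):
            raise ValueError(
                f"provider returned {len(lemmas)} lemmas for {len(words)} words"
            )
    except Exception:
        lemmas = []
        for w in words:
            try:
                lemmas.append(provider([w])[0])
            except Exception:
                logger.warning("lemma provider failed on %r; using lowercased text", w)
                lemmas.append(w.lower())
    for tok, lemma in zip(tokens, lemmas):
        tok.lemma = lemma if lemma else tok.text.lower()
    return tokens
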