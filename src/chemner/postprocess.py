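"""BIO-to-mention conversion and corpus-independent postprocessing rules.

Two general rules: (1) drop any mention whose text carries mismatched
parentheses, brackets or double quotation marks; (2) resolve abbreviations
defined as ``long form (SF)`` so that short and long form are tagged
consistently.
"""

from __future__ import annotations

import re
from typing import Sequence

from .corpus_io import Document, Mention
from .preprocessing import Token

__all__ = [
    "merge_bio",
    "is_balanced",
    "filter_unbalanced",
    "resolve_abbreviations",
    "mentions_to_bio",
]

_OPEN = {"(": ")", "[": "]", "{": "}"}
_CLOSE = {")": "(", "]": "[", "}": "{"}


def merge_bio(
    tokens: Sequence[Token],
    labels: Sequence[str],
    *,
    doc_id: str,
    section: str,
    text: str,
    confidences: Sequence[float] | None = None,
) -> list[Mention]:
    """Merge maximal B-X (I-X)* runs into mentions in section coordinates.

    An I-X with no preceding B-X/I-X of the same type is promoted to B-X.
    A mention's confidence is the minimum over its tokens' confidences.
    """
    if len(tokens) != len(labels):
        raise ValueError("labels and tokens differ in length")
    mentions: list[Mention] = []
    run: list[int] = []
    run_type: str | None = None

    def flush() -> None:
        nonlocal run, run_type
        if run:
            start = tokens[run[0]].start
            end = tokens[run[-1]].end
            conf = 1.0
            if confidences is not None:
                conf = min(confidences[i] for i in run)
            mentions.append(
                Mention(doc_id, section, start, end, text[start:end], run_type, conf)
            )
        run, run_type = [], None

    for i, lab in enumerate(labels):
        if lab == "O":
            flush()
            continue
        etype = lab[2:]
        if lab.startswith("B-") or etype != run_type:
            flush()
        run.append(i)
        run_type = etype
    flush()
    return mentions


def mentions_to_bio(
    tokens: Sequence[Token], mentions: Sequence[Mention], entity_type: str | None = None
) -> list[str]:
    """Project mention character spans onto tokens as BIO labels.

    A token is inside a mention when its span overlaps the mention span;
    the first such token gets B-, the rest I-.
    """
    labels = ["O"] * len(tokens)
    for m in sorted(mentions, key=lambda m: (m.start, m.end)):
        etype = entity_type or m.entity_type
        first = True
        for i, tok in enumerate(tokens):
            if tok.start < m.end and tok.end > m.start:
                labels[i] = ("B-" if first else "I-") + etype
                first = False
    return labels


def is_balanced(text: str) -> bool:
    """Stack-matched (), [], {} and an even number of double quotes."""
    stack: list[str] = []
    for ch in text:
        if ch in _OPEN:
            stack.append(ch)
        elif ch in _CLOSE:
            if not stack or stack[-1] != _CLOSE[ch]:
                return False
            stack.pop()
    return not stack and text.count('"') % 2 == 0


def filter_unbalanced(mentions: Sequence[Mention]) -> list[Mention]:
    """Drop mentions with mismatched parentheses/brackets/double quotes."""
    return [m for m in mentions if is_balanced(m.text)]


_PAREN = re.compile(r"\(([^()]{1,10})\)")


def _short_form_ok(sf: str) -> bool:
    return 1 <= len(sf) <= 10 and any(ch.isalpha() for ch in sf)


def _find_long_form(text: str, open_paren: int, sf: str) -> tuple[int, int] | None:
    """Match the short form's letters in order, right-to-left, in the text
    before the parenthesis; the first letter must start a word."""
    letters = [ch.lower() for ch in sf if ch.isalnum()]
    if not letters:
        return None
    end = open_paren
    while end > 0 and text[end - 1].isspace():
        end -= 1
    if end == 0:
        return None
    # limit the search window, as is conventional for SF/LF matching
    max_words = min(len(letters) + 5, len(letters) * 2)
    i = end
    li = len(letters) - 1
    start = None
    words_seen = 0
    while i > 0 and li >= 0:
        i -= 1
        ch = text[i].lower()
        if text[i].isspace():
            words_seen += 1
            if words_seen > max_words:
                return None
        if ch == letters[li]:
            # the first letter must sit at a word boundary
            if li == 0:
                if i == 0 or not text[i - 1].isalnum():
                    start = i
                    li -= 1
                # else keep scanning left for an earlier word start
            else:
                li -= 1
    if start is None or li >= 0:
        return None
    return (start, end)


def resolve_abbreviations(
    document: Document, mentions: Sequence[Mention]
) -> list[Mention]:
    """Propagate tags across ``long form (SF)`` definition patterns.

    If the long form overlaps a tagged mention but the short form is
    untagged, a mention over the short form is added (same type, inherited
    confidence), and symmetrically for a tagged short form with an untagged
    long form. Mentions are never removed; the operation is idempotent.
    """
    out = list(mentions)
    for section in ("T", "A"):
        text = document.section_text(section)
        existing = [m for m in out if m.section == section]

        def covered(start: int, end: int) -> Mention | None:
            for m in existing:
                if m.start < end and m.end > start:
                    return m
            return None

        additions: list[Mention] = []
        for pm in _PAREN.finditer(text):
            sf = pm.group(1)
            if not _short_form_ok(sf):
                continue
            lf_span = _find_long_form(text, pm.start(), sf)
            if lf_span is None:
                continue
            sf_start, sf_end = pm.start(1), pm.end(1)
            lf_m = covered(*lf_span)
            sf_m = covered(sf_start, sf_end)
            if lf_m is not None and sf_m is None:
                additions.append(
                    Mention(
                        document.doc_id,
                        section,
                        sf_start,
                        sf_end,
                        text[sf_start:sf_end],
                        lf_m.entity_type,
                        lf_m.confidence,
                    )
                )
            elif sf_m is not None and lf_m is None:
                additions.append(
                    Mention(
                        document.doc_id,
                        section,
                        lf_span[0],
                        lf_span[1],
                        text[lf_span[0] : lf_span[1]],
                        sf_m.entity_type,
                        sf_m.confidence,
                    )
                )
        seen = {m.key() for m in out}
        for m in additions:
            if m.key() not in seen:
                out.append(m)
                seen.add(m.key())
    return out
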