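"""Reading and writing annotated corpora, predictions, and BIO token files.

The labeled-corpus layout follows the BioCreative distribution convention:
an *abstracts* file with one tab-separated record per document
(``doc_id<TAB>title<TAB>abstract``) and an *annotations* file with one
mention per line (``doc_id<TAB>section<TAB>start<TAB>end<TAB>text<TAB>type``).
Offsets are 0-based half-open character offsets into the raw title (section
``T``) or abstract (section ``A``); title and abstract are independent
offset spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Document",
    "Mention",
    "AnnotatedCorpus",
    "CorpusFormatError",
    "read_abstracts",
    "write_abstracts",
    "read_annotations",
    "write_annotations",
    "write_predictions",
    "read_predictions",
    "read_bio",
    "write_bio",
]

SECTIONS = ("T", "A")


class CorpusFormatError(ValueError):
    """Raised for malformed corpus, annotation, or BIO files."""


@dataclass(frozen=True)
class Document:
    """A title+abstract record identified by a PMID-like id."""

    doc_id: str
    title: str
    abstract: str

    def section_text(self, section: str) -> str:
        if section == "T":
            return self.title
        if section == "A":
            return self.abstract
        raise ValueError(f"unknown section {section!r} (expected T or A)")


@dataclass(frozen=True, order=True)
class Mention:
    """An entity mention located by character offsets in one section.

    ``start``/``end`` are 0-based half-open offsets into the raw section
    text; ``text`` must equal that substring exactly.
    """

    doc_id: str
    section: str
    start: int
    end: int
    text: str
    entity_type: str = "CHEM"
    confidence: float = 1.0

    def key(self) -> tuple:
        return (self.doc_id, self.section, self.start, self.end)


@dataclass
class AnnotatedCorpus:
    documents: list[Document] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_id = {}
        for doc in self.documents:
            if not doc.doc_id:
                raise CorpusFormatError("empty doc_id")
            if doc.doc_id in by_id:
                raise CorpusFormatError(f"duplicate doc_id {doc.doc_id!r}")
            by_id[doc.doc_id] = doc
        seen = set()
        for m in self.mentions:
            validate_mention(m, by_id)
            k = (m.doc_id, m.section, m.start, m.end, m.entity_type)
            if k in seen:
                raise CorpusFormatError(f"duplicate mention {k}")
            seen.add(k)

    @property
    def documents_by_id(self) -> dict[str, Document]:
        return {d.doc_id: d for d in self.documents}

    def mentions_for(self, doc_id: str, section: str | None = None) -> list[Mention]:
        return [
            m
            for m in self.mentions
            if m.doc_id == doc_id and (section is None or m.section == section)
        ]


def validate_mention(m: Mention, documents_by_id: dict[str, Document]) -> None:
    if m.doc_id not in documents_by_id:
        raise CorpusFormatError(f"mention references unknown doc_id {m.doc_id!r}")
    if m.section not in SECTIONS:
        raise CorpusFormatError(
            f"doc {m.doc_id}: unknown section {m.section!r} (expected T or A)"
        )
    text = documents_by_id[m.doc_id].section_text(m.section)
    if not (0 <= m.start < m.end <= len(text)):
        raise CorpusFormatError(
            f"doc {m.doc_id}: offsets {m.start}:{m.end} out of range for "
            f"section {m.section} (length {len(text)})"
        )
    if text[m.start : m.end] != m.text:
        raise CorpusFormatError(
            f"doc {m.doc_id}: text mismatch at {m.section}:{m.start}:{m.end}: "
            f"annotation {m.text!r} vs source {text[m.start:m.end]!r}"
        )
    if not (0.0 <= m.confidence <= 1.0):
        raise CorpusFormatError(
            f"doc {m.doc_id}: confidence {m.confidence} outside [0, 1]"
        )


def read_abstracts(path) -> list[Document]:
    """Read a 3-column tab-separated abstracts file."""
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            doc_id, title, abstract = fields
            if doc_id in seen:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: duplicate doc_id {doc_id!r}"
                )
            seen.add(doc_id)
            docs.append(Document(doc_id, title, abstract))
    return docs


def write_abstracts(documents: Iterable[Document], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in documents:
            fh.write(f"{d.doc_id}\t{d.title}\t{d.abstract}\n")


def read_annotations(path, corpus: Sequence[Document]) -> list[Mention]:
    """Read a 6-column annotations file, validating every mention against
    the documents (offset range and substring identity)."""
    by_id = {d.doc_id: d for d in corpus}
    mentions: list[Mention] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            doc_id, section, start_s, end_s, text, etype = fields
            if section not in SECTIONS:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: section must be T or A, got {section!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: non-integer offsets"
                ) from exc
            m = Mention(doc_id, section, start, end, text, etype)
            validate_mention(m, by_id)
            mentions.append(m)
    return mentions


def write_annotations(mentions: Iterable[Mention], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                f"{m.doc_id}\t{m.section}\t{m.start}\t{m.end}\t{m.text}\t{m.entity_type}\n"
            )


def _ranked(items: list[tuple], doc_ids: list[str]) -> Iterable[tuple]:
    """Yield rows grouped by doc in first-seen order, ranked 1-based per doc
    by descending confidence; ties broken by ascending (start, text)."""
    for doc_id in doc_ids:
        rows = [it for it in items if it[0] == doc_id]
        rows.sort(key=lambda it: (-it[1], it[2], it[3]))
        for rank, it in enumerate(rows, start=1):
            yield it, rank


def write_predictions(mentions: Sequence[Mention], task: str, path) -> None:
    """Write CEM (``doc<TAB>S:start:end<TAB>rank<TAB>conf``) or CDI
    (``doc<TAB>text<TAB>rank<TAB>conf``) prediction files.

    CDI rows are unique per (doc_id, text) with confidence equal to the
    maximum over that string's mentions. Ranks are 1-based per document by
    descending confidence, ties by ascending (start, text).
    """
    task = task.upper()
    if task not in ("CEM", "CDI"):
        raise ValueError(f"task must be CEM or CDI, got {task!r}")
    doc_ids: list[str] = []
    for m in mentions:
        if m.doc_id not in doc_ids:
            doc_ids.append(m.doc_id)
    with open(path, "w", encoding="utf-8") as fh:
        if task == "CEM":
            items = [
                (m.doc_id, m.confidence, m.start, m.text, m.section, m.end)
                for m in mentions
            ]
            for (doc_id, conf, start, _text, sec, end), rank in _ranked(items, doc_ids):
                fh.write(f"{doc_id}\t{sec}:{start}:{end}\t{rank}\t{conf:g}\n")
        else:
            best: dict[tuple[str, str], tuple[float, int]] = {}
            for m in mentions:
                k = (m.doc_id, m.text)
                prev = best.get(k)
                cand = (m.confidence, m.start)
                if prev is None:
                    best[k] = cand
                else:
                    best[k] = (max(prev[0], cand[0]), min(prev[1], cand[1]))
            items = [
                (doc_id, conf, start, text)
                for (doc_id, text), (conf, start) in best.items()
            ]
            for (doc_id, conf, _start, text), rank in _ranked(items, doc_ids):
                fh.write(f"{doc_id}\t{text}\t{rank}\t{conf:g}\n")


def read_predictions(path, task: str) -> list[tuple]:
    """Parse a prediction file back into match keys.

    Returns ``(doc_id, section, start, end)`` tuples for CEM and
    ``(doc_id, text)`` tuples for CDI, in file order.
    """
    task = task.upper()
    out: list[tuple] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(fields)}"
                )
            if task == "CEM":
                loc = fields[1].split(":")
                if len(loc) != 3 or loc[0] not in SECTIONS:
                    raise CorpusFormatError(
                        f"{path}: line {lineno}: bad CEM location {fields[1]!r}"
                    )
                out.append((fields[0], loc[0], int(loc[1]), int(loc[2])))
            else:
                out.append((fields[0], fields[1]))
    return out


def _check_bio_label(label: str, path, lineno: int) -> None:
    if label == "O":
        return
    if (label.startswith("B-") or label.startswith("I-")) and len(label) > 2:
        return
    raise CorpusFormatError(
        f"{path}: line {lineno}: label {label!r} outside the BIO alphabet"
    )


def read_bio(path) -> list[tuple[list[str], list[str]]]:
    """Read a token-per-line BIO file; blank lines separate sentences."""
    sentences: list[tuple[list[str], list[str]]] = []
    tokens: list[str] = []
    labels: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                if tokens:
                    sentences.append((tokens, labels))
                    tokens, labels = [], []
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected token<TAB>label"
                )
            _check_bio_label(fields[1], path, lineno)
            tokens.append(fields[0])
            labels.append(fields[1])
    if tokens:
        sentences.append((tokens, labels))
    return sentences


def write_bio(sentences: Iterable[tuple[Sequence[str], Sequence[str]]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tokens, labels in sentences:
            for tok, lab in zip(tokens, labels):
                fh.write(f"{tok}\t{lab}\n")
            fh.write("\n")
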