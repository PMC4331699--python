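"""Synthetic corpora with the statistical structure the tagger exploits.

Two generators:

* :func:`gen_labeled_corpus` builds title+abstract documents from carrier
  sentence templates with two kinds of content slot: chemical-context
  slots (after "treated with", "addition of", ...) and plain noun slots
  ("the ... samples"). Chemical slots are filled either with
  grammar-generated chemical-like names (digit locants, stereo modifiers,
  stems, nomenclature suffixes such as -ol/-ane/-ene/-ate/-ide/-ine) or
  with *pseudo-chemical* distractor words that share the same suffix
  shapes but are never entities; noun slots draw from both distractor
  vocabularies. Gold character offsets are recorded exactly. The entity
  grammar is combinatorial and the distractor vocabularies are sampled
  with a long-tailed (Zipf-like) law, so held-out documents contain both
  entity strings and distractor words never seen in a small training set:
  surface shape alone cannot decide entity-hood there, while a word's
  distribution across a large unlabeled corpus can — the situation in
  which word-representation features earn their keep.
* :func:`gen_class_lm_corpus` samples an unlabeled token stream from a
  latent-class bigram language model (near-permutation class transitions,
  uniform within-class emission), returning the generator's word->class
  map so that Brown clustering and word-vector-class induction can be
  tested for exact recovery.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .corpus_io import AnnotatedCorpus, Document, Mention

__all__ = [
    "gen_labeled_corpus",
    "gen_class_lm_corpus",
    "split_corpus",
    "corpus_text_lines",
]

_LOCANTS = ["", "", "", "2-", "3-", "4-", "1,2-", "N-"]
_MODIFIERS = ["", "", "", "", "(R)-", "(S)-"]
_STEMS = [
    "meth", "eth", "prop", "but", "pent", "hex", "hept", "oct", "benz",
    "tolu", "phen", "chlor", "fluor", "brom", "iod", "amin", "hydrox",
    "oxal", "carb", "sulf", "nitr", "glyc", "acet", "form", "malon",
]
_INFIXES = ["", "", "", "yl", "oxy", "an"]
_SUFFIXES = ["ol", "ane", "ene", "ate", "ide", "ine"]
_SALTS = ["sodium", "potassium", "calcium", "ammonium"]

# stems for distractor words; disjoint from the entity grammar's stems
_PSEUDO_STEMS = [
    "memb", "sal", "prote", "recept", "bas", "rout", "cultur", "grad",
    "fract", "neur", "muscl", "hepat", "ren", "cortic", "plasm", "ser",
    "enzym", "buff", "substr", "pept", "nucle", "vesic", "cytos", "rib",
    "lys", "mit", "fibr", "vascul", "derm", "oss",
]
_PSEUDO_INFIXES = ["", "", "o", "ul", "er", "an"]

_PLAIN_DISTRACTORS = [
    "tissue", "sample", "liver", "kidney", "cell", "cortex", "tumor",
    "pathway", "signal", "response", "medium", "control", "assay",
    "marker", "extract", "mixture", "reaction", "solution", "surface",
    "animal", "patient", "group", "model", "effect", "activity",
]


def _make_pseudo_chemicals(n: int) -> list[str]:
    """A fixed vocabulary of chemical-shaped words that are never entities.

    Built deterministically (own internal seed) so every corpus drawn with
    any seed shares the same vocabulary.
    """
    rng = np.random.RandomState(1234)
    out: list[str] = []
    seen = set()
    while len(out) < n:
        w = (
            _PSEUDO_STEMS[rng.randint(len(_PSEUDO_STEMS))]
            + _PSEUDO_INFIXES[rng.randint(len(_PSEUDO_INFIXES))]
            + _SUFFIXES[rng.randint(len(_SUFFIXES))]
        )
        if w not in seen:
            seen.add(w)
            out.append(w)
    return out


def _zipf_probs(n: int, s: float = 1.1) -> np.ndarray:
    p = 1.0 / np.arange(2, n + 2) ** s
    return p / p.sum()


# carrier templates: literal tokens, "E" = chemical-context slot,
# "N" = plain noun slot
_TITLE_TEMPLATES = [
    ["Effects", "of", "E", "on", "N", "function"],
    ["Analysis", "of", "E", "in", "N", "samples"],
    ["Determination", "of", "E", "by", "chromatography"],
    ["Role", "of", "E", "in", "the", "N", "response"],
]
_SENT_TEMPLATES = [
    ["We", "treated", "the", "N", "with", "E", "."],
    ["The", "E", "level", "was", "measured", "in", "the", "N", "."],
    ["Exposure", "to", "E", "increased", "N", "activity", "."],
    ["Addition", "of", "E", "and", "E", "reduced", "the", "signal", "."],
    ["The", "binding", "of", "E", "to", "the", "N", "was", "assessed", "."],
    ["Samples", "were", "incubated", "with", "E", "for", "two", "hours", "."],
    ["No", "effect", "of", "E", "on", "the", "N", "was", "observed", "."],
]
_ALL_TEMPLATES = _TITLE_TEMPLATES + _SENT_TEMPLATES


def _entity_string(rng: np.random.RandomState, stems: list[str]) -> str:
    name = (
        _MODIFIERS[rng.randint(len(_MODIFIERS))]
        + _LOCANTS[rng.randint(len(_LOCANTS))]
        + stems[rng.randint(len(stems))]
        + _INFIXES[rng.randint(len(_INFIXES))]
        + _SUFFIXES[rng.randint(len(_SUFFIXES))]
    )
    form = rng.rand()
    if form < 0.12:
        return _SALTS[rng.randint(len(_SALTS))] + " " + name
    if form < 0.2:
        return name + " " + ["chloride", "acid", "ester"][rng.randint(3)]
    return name


_MEAN_ENTITY_TOKENS = 1.2  # 20% of entity strings are two-token forms


def _entity_slot_prob(entity_density: float) -> float:
    """Per-chemical-slot entity probability yielding the requested fraction
    of entity tokens under the shipped template set."""
    n_fixed = sum(sum(1 for w in t if w not in ("E", "N")) for t in _ALL_TEMPLATES)
    n_e = sum(sum(1 for w in t if w == "E") for t in _ALL_TEMPLATES)
    n_n = sum(sum(1 for w in t if w == "N") for t in _ALL_TEMPLATES)
    k = len(_ALL_TEMPLATES)
    fbar, ebar, nbar = n_fixed / k, n_e / k, n_n / k
    m = _MEAN_ENTITY_TOKENS
    # solve d = ebar*p*m / (fbar + nbar + ebar*(p*m + 1 - p)) for p
    d = entity_density
    denom = ebar * m - d * ebar * (m - 1)
    p = d * (fbar + nbar + ebar) / denom
    return float(min(0.95, max(0.01, p)))


class _Vocab:
    """Resolved slot-filling distributions for one corpus draw."""

    def __init__(self, params: dict, entity_density: float):
        self.stems = list(params.get("stems", _STEMS))
        self.pseudo = _make_pseudo_chemicals(int(params.get("n_pseudo", 150)))
        self.plain = list(params.get("plain_distractors", _PLAIN_DISTRACTORS))
        self.pseudo_probs = _zipf_probs(len(self.pseudo))
        self.p_entity = _entity_slot_prob(entity_density)

    def _pseudo(self, rng: np.random.RandomState) -> str:
        return self.pseudo[rng.choice(len(self.pseudo), p=self.pseudo_probs)]

    def fill(self, kind: str, rng: np.random.RandomState) -> tuple[str, bool]:
        """Return (text, is_entity) for one slot of the given kind.

        Pseudo-chemicals appear in both slot kinds but predominantly in
        noun slots, so a word's corpus-wide context distribution — not its
        surface shape — is what marks it as a non-entity.
        """
        if kind == "E":
            if rng.rand() < self.p_entity:
                return _entity_string(rng, self.stems), True
            if rng.rand() < 0.35:
                return self._pseudo(rng), False
            return self.plain[rng.randint(len(self.plain))], False
        # noun slot: half plain nouns, half pseudo-chemicals
        if rng.rand() < 0.5:
            return self._pseudo(rng), False
        return self.plain[rng.randint(len(self.plain))], False


def _fill_template(
    template: list[str], rng: np.random.RandomState, vocab: _Vocab
) -> tuple[str, list[tuple[int, int, str]]]:
    """Render one template; returns (text, [(start, end, text), ...])."""
    parts: list[str] = []
    spans: list[tuple[int, int, str]] = []
    pos = 0
    for i, item in enumerate(template):
        if i > 0 and item not in (".", ","):
            parts.append(" ")
            pos += 1
        if item in ("E", "N"):
            word, is_entity = vocab.fill(item, rng)
            if is_entity:
                spans.append((pos, pos + len(word), word))
            parts.append(word)
            pos += len(word)
        else:
            parts.append(item)
            pos += len(item)
    return "".join(parts), spans


def gen_labeled_corpus(
    seed: int,
    n_docs: int,
    entity_density: float = 0.15,
    vocab_params: dict | None = None,
) -> AnnotatedCorpus:
    """Generate an annotated corpus of chemical-like mentions with exact
    gold offsets. Deterministic under ``seed``."""
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    if not 0.0 < entity_density < 1.0:
        raise ValueError("entity_density must lie in (0, 1)")
    params = vocab_params or {}
    vocab = _Vocab(params, entity_density)
    sents_low = int(params.get("min_sentences", 2))
    sents_high = int(params.get("max_sentences", 4))

    rng = np.random.RandomState(seed)
    documents: list[Document] = []
    mentions: list[Mention] = []
    for d in range(n_docs):
        doc_id = f"{10000000 + d}"
        t_template = _TITLE_TEMPLATES[rng.randint(len(_TITLE_TEMPLATES))]
        title, t_spans = _fill_template(t_template, rng, vocab)
        abstract_parts: list[str] = []
        a_spans: list[tuple[int, int, str]] = []
        pos = 0
        for s in range(rng.randint(sents_low, sents_high + 1)):
            if s > 0:
                abstract_parts.append(" ")
                pos += 1
            sent, spans = _fill_template(
                _SENT_TEMPLATES[rng.randint(len(_SENT_TEMPLATES))], rng, vocab
            )
            a_spans.extend((a + pos, b + pos, t) for a, b, t in spans)
            abstract_parts.append(sent)
            pos += len(sent)
        abstract = "".join(abstract_parts)
        documents.append(Document(doc_id, title, abstract))
        for a, b, t in t_spans:
            mentions.append(Mention(doc_id, "T", a, b, t, "CHEM"))
        for a, b, t in a_spans:
            mentions.append(Mention(doc_id, "A", a, b, t, "CHEM"))
    return AnnotatedCorpus(documents=documents, mentions=mentions)


def gen_class_lm_corpus(
    seed: int,
    n_classes: int,
    words_per_class: int,
    n_tokens: int,
    switch_noise: float = 0.05,
    line_length: int = 20,
) -> tuple[list[list[str]], dict[str, int]]:
    """Sample a token stream from a latent-class bigram chain.

    The class transition matrix is a cyclic permutation softened by
    ``switch_noise`` (the strong-separation preset uses small noise);
    emission within a class is uniform. Returns the token lines and the
    generating word->class map for recovery tests.
    """
    if n_classes < 2 or words_per_class < 1 or n_tokens < 1:
        raise ValueError("parameters must be positive (n_classes >= 2)")
    rng = np.random.RandomState(seed)
    words = [[f"c{c}w{k}" for k in range(words_per_class)] for c in range(n_classes)]
    word_to_class = {w: c for c, ws in enumerate(words) for w in ws}

    off = switch_noise / max(1, n_classes - 1)
    trans = np.full((n_classes, n_classes), off)
    for c in range(n_classes):
        trans[c, (c + 1) % n_classes] = 1.0 - switch_noise
        trans[c, c] = off
    trans /= trans.sum(axis=1, keepdims=True)

    lines: list[list[str]] = []
    line: list[str] = []
    c = int(rng.randint(n_classes))
    for _ in range(n_tokens):
        line.append(words[c][rng.randint(words_per_class)])
        if len(line) >= line_length:
            lines.append(line)
            line = []
        c = int(rng.choice(n_classes, p=trans[c]))
    if line:
        lines.append(line)
    return lines, word_to_class


def split_corpus(
    corpus: AnnotatedCorpus, n_train: int, n_test: int
) -> tuple[AnnotatedCorpus, AnnotatedCorpus]:
    """Document-disjoint head/tail split."""
    if n_train + n_test > len(corpus.documents):
        raise ValueError("split larger than corpus")
    train_docs = corpus.documents[:n_train]
    test_docs = corpus.documents[n_train : n_train + n_test]
    train_ids = {d.doc_id for d in train_docs}
    test_ids = {d.doc_id for d in test_docs}
    return (
        AnnotatedCorpus(
            documents=train_docs,
            mentions=[m for m in corpus.mentions if m.doc_id in train_ids],
        ),
        AnnotatedCorpus(
            documents=test_docs,
            mentions=[m for m in corpus.mentions if m.doc_id in test_ids],
        ),
    )


def corpus_text_lines(corpus: AnnotatedCorpus) -> list[str]:
    """One plain-text line per document (title + abstract), e.g. as input
    for representation induction."""
    return [f"{d.title} {d.abstract}".strip() for d in corpus.documents]
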