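"""End-to-end tagging pipeline: preprocessing, features, CRF, postprocessing.

The supervised path tokenizes the raw section text (simple tokenizer by
default) so gold offsets stay valid; representation induction elsewhere
uses cleansed, whitespace-tokenized text. Mention confidences are the
minimum forward-backward posterior of the decoded label over the mention's
tokens, which feeds the ranked CEM/CDI output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import crf as _crf
from .corpus_io import AnnotatedCorpus, Document, Mention
from .features import FeatureConfig, RepresentationModels, assemble
from .postprocess import (
    filter_unbalanced,
    mentions_to_bio,
    merge_bio,
    resolve_abbreviations,
)
from .preprocessing import (
    Token,
    lemmatize,
    split_sentences,
    tokenize_simple,
    tokenize_whitespace,
)

__all__ = [
    "Tagger",
    "TaggerConfig",
    "train_tagger",
    "tag_document",
    "tag_corpus",
    "induce_representations",
]

_TOKENIZERS = {"simple": tokenize_simple, "whitespace": tokenize_whitespace}


@dataclass
class TaggerConfig:
    tokenizer: str = "simple"
    features: FeatureConfig = field(default_factory=FeatureConfig)
    sigma: float = 1.0
    tolerance: float = 1e-4
    max_iter: int = 100
    postprocess: bool = True


@dataclass
class Tagger:
    config: TaggerConfig
    models: RepresentationModels
    crf: _crf.CRFModel


def _section_sentences(text: str, tokenizer) -> list[list[Token]]:
    """Tokenized, lemmatized sentences with offsets in section coordinates."""
    sentences = []
    for a, b in split_sentences(text):
        toks = tokenizer(text[a:b])
        for t in toks:
            t.start += a
            t.end += a
        if toks:
            lemmatize(toks)
            sentences.append(toks)
    return sentences


def _labeled_sequences(
    corpus: AnnotatedCorpus, config: TaggerConfig, models: RepresentationModels
) -> list[_crf.LabeledSequence]:
    tokenizer = _TOKENIZERS[config.tokenizer]
    out = []
    for doc in corpus.documents:
        for section in ("T", "A"):
            text = doc.section_text(section)
            gold = corpus.mentions_for(doc.doc_id, section)
            for toks in _section_sentences(text, tokenizer):
                labels = mentions_to_bio(toks, gold)
                fvs = assemble(toks, config.features, models)
                out.append(_crf.LabeledSequence(fvs, labels))
    return out


def train_tagger(
    corpus: AnnotatedCorpus,
    config: TaggerConfig | None = None,
    models: RepresentationModels | None = None,
) -> Tagger:
    config = config or TaggerConfig()
    models = models or RepresentationModels()
    data = _labeled_sequences(corpus, config, models)
    model = _crf.train(
        data,
        sigma=config.sigma,
        tolerance=config.tolerance,
        max_iter=config.max_iter,
    )
    return Tagger(config=config, models=models, crf=model)


def tag_document(tagger: Tagger, doc: Document) -> list[Mention]:
    tokenizer = _TOKENIZERS[tagger.config.tokenizer]
    mentions: list[Mention] = []
    for section in ("T", "A"):
        text = doc.section_text(section)
        for toks in _section_sentences(text, tokenizer):
            fvs = assemble(toks, tagger.config.features, tagger.models)
            labels, _lp = _crf.viterbi(tagger.crf, fvs)
            post = _crf.marginals(tagger.crf, fvs)
            confs = [
                float(post[t, tagger.crf.label_id(lab)])
                for t, lab in enumerate(labels)
            ]
            mentions.extend(
                merge_bio(
                    toks,
                    labels,
                    doc_id=doc.doc_id,
                    section=section,
                    text=text,
                    confidences=confs,
                )
            )
    if tagger.config.postprocess:
        mentions = filter_unbalanced(mentions)
        mentions = resolve_abbreviations(doc, mentions)
    return mentions


def tag_corpus(tagger: Tagger, documents: list[Document]) -> list[Mention]:
    out: list[Mention] = []
    for doc in documents:
        out.extend(tag_document(tagger, doc))
    return out


def induce_representations(
    lines: list[str],
    brown_k: int = 16,
    wvc_sizes: tuple[int, ...] = (),
    wv_config=None,
    min_count: int = 2,
    kmeans_seed: int = 0,
) -> RepresentationModels:
    """Build Brown and word-vector-class models from unlabeled text.

    ``lines`` is plain text, one document per line; it is cleansed and
    whitespace-tokenized (the representation-induction defaults) before
    counting. ``wv_config`` defaults to a desk-scale configuration and is
    required when ``wvc_sizes`` is non-empty.
    """
    from . import brown as _brown
    from . import wordrep as _wordrep
    from .preprocessing import cleanse as _cleanse

    token_lines = [
        [t.text for t in tokenize_whitespace(_cleanse(line))] for line in lines
    ]
    models = RepresentationModels()
    if brown_k:
        counts = _brown.collect_bigrams(token_lines, min_count=min_count)
        models.brown = _brown.induce(counts, brown_k)
    if wvc_sizes:
        cfg = wv_config or _wordrep.WVConfig(
            dimension=25, epochs=3, mode="skipgram", min_count=min_count
        )
        wv = _wordrep.train_wv(token_lines, cfg)
        models.wv = wv
        for size in wvc_sizes:
            models.wvcs[size] = _wordrep.kmeans(wv, size, seed=kmeans_seed)
    return models
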