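"""Baseline feature templates and per-token feature-vector assembly.

The baseline set comprises the word, its lemma, orthographic shape patterns
(full-match regular expressions), 2/3/4-character prefixes and suffixes,
boundary-marked 2/3-character n-grams, and 2/3-word n-grams. Every
token-level template is replicated across a two-token sliding window
(offsets -2..+2); positions beyond the sentence contribute a single PAD
sentinel. Word-representation features (Brown bit-string prefixes,
word-vector-class ids) plug in through the same window.

Feature keys are plain strings of the form ``TEMPLATE@offset=value`` — no
hashing, so feature files are directly auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .brown import BrownModel
    from .preprocessing import Token
    from .wordrep import WordVectorModel, WVCModel

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "RepresentationModels",
    "ConfigurationError",
    "ORTHOGRAPHIC_PATTERNS",
    "orthographic_features",
    "affix_features",
    "char_ngrams",
    "word_ngrams",
    "assemble",
]


class ConfigurationError(ValueError):
    """A feature configuration references a model that was not supplied."""


# Whole-token shape patterns, applied with FULL-match semantics.
ORTHOGRAPHIC_PATTERNS: dict[str, re.Pattern] = {
    "ROMAN": re.compile(r"[ivxdlcm]+|[IVXDLCM]+"),
    "PUNCT": re.compile(r"[,\.;:?!]"),
    "NUCLEO": re.compile(r"[atgcu]+"),
    "NUM": re.compile(r"[0-9]+"),
    "INITCAP": re.compile(r"[A-Z][a-z]*"),
    "QUOTE": re.compile(r"[\"`']"),
}


@dataclass
class FeatureConfig:
    """Which templates fire and with which parameters."""

    window: int = 2
    affix_lengths: tuple[int, ...] = (2, 3, 4)
    char_ngram_lengths: tuple[int, ...] = (2, 3)
    word_ngram_lengths: tuple[int, ...] = (2, 3)
    brown_prefix_lengths: tuple[int, ...] = (4, 6, 10, 20)
    wvc_model_sizes: tuple[int, ...] = ()
    use_brown: bool = False
    use_pos: bool = False
    use_raw_wv: bool = False


@dataclass
class FeatureVector:
    """The string feature keys active for one token position."""

    position: int
    features: set[str] = field(default_factory=set)


@dataclass
class RepresentationModels:
    """Container for the unsupervised models feeding window features."""

    brown: "BrownModel | None" = None
    wvcs: dict[int, "WVCModel"] = field(default_factory=dict)
    wv: "WordVectorModel | None" = None


def orthographic_features(token_text: str) -> set[str]:
    """Names of the orthographic patterns that full-match the token.

    DASHSTART additionally fires when the token starts with ``-``.
    """
    out = {
        name for name, pat in ORTHOGRAPHIC_PATTERNS.items() if pat.fullmatch(token_text)
    }
    if token_text.startswith("-"):
        out.add("DASHSTART")
    return out


def affix_features(
    token_text: str, lengths: Sequence[int] = (2, 3, 4)
) -> set[str]:
    """``PREn=``/``SUFn=`` keys; lengths exceeding the token are omitted."""
    out = set()
    for n in lengths:
        if len(token_text) >= n:
            out.add(f"PRE{n}={token_text[:n]}")
            out.add(f"SUF{n}={token_text[-n:]}")
    return out


def char_ngrams(token_text: str, n: int) -> set[str]:
    """Character n-grams over the token flanked by ``^``/``$`` sentinels."""
    s = "^" + token_text + "$"
    return {s[i : i + n] for i in range(len(s) - n + 1)}


def word_ngrams(texts: Sequence[str], i: int, n: int) -> set[str]:
    """Word n-grams covering position ``i``, joined with ``_`` and annotated
    with the covered token's alignment inside the gram."""
    out = set()
    for j in range(max(0, i - n + 1), min(i, len(texts) - n) + 1):
        gram = "_".join(texts[j : j + n])
        out.add(f"WNG{n}[{i - j}]={gram}")
    return out


def _token_features(tok: "Token", config: FeatureConfig) -> set[str]:
    """Window-template features of a single token (without offset tags)."""
    feats = {f"W={tok.text}"}
    if tok.lemma:
        feats.add(f"LEM={tok.lemma}")
    if config.use_pos and tok.pos:
        feats.add(f"POS={tok.pos}")
    feats.update(f"ORTHO={name}" for name in orthographic_features(tok.text))
    feats.update(affix_features(tok.text, config.affix_lengths))
    for n in config.char_ngram_lengths:
        feats.update(f"CG{n}={g}" for g in char_ngrams(tok.text, n))
    return feats


def _representation_features(
    tok: "Token", config: FeatureConfig, models: RepresentationModels
) -> set[str]:
    from .brown import prefix_feature
    from .wordrep import wvc_feature

    feats: set[str] = set()
    if config.use_brown:
        if models.brown is None:
            raise ConfigurationError("config requests Brown features but no model given")
        for L in config.brown_prefix_lengths:
            feats.add(f"BROWN{L}={prefix_feature(models.brown, tok.text, L)}")
    for size in config.wvc_model_sizes:
        if size not in models.wvcs:
            raise ConfigurationError(
                f"config requests WVC model of size {size} but it was not supplied"
            )
        feats.add(wvc_feature(models.wvcs[size], tok.text, f"WVC{size}"))
    return feats


def assemble(
    tokens: Sequence["Token"],
    config: FeatureConfig | None = None,
    models: RepresentationModels | None = None,
) -> list[FeatureVector]:
    """Build one FeatureVector per token with the sliding-window expansion.

    For each position ``i`` and offset ``d`` in ``-window..+window``, the
    token-level features of token ``i+d`` are tagged ``@d``; out-of-sentence
    positions contribute a ``PAD@d`` sentinel. Word n-grams are anchored at
    ``i`` only. Raw word-vector dimensions are emitted only when
    ``use_raw_wv`` is set and a vector model is supplied.
    """
    config = config or FeatureConfig()
    models = models or RepresentationModels()
    if config.use_raw_wv and models.wv is None:
        raise ConfigurationError("use_raw_wv set but no word-vector model supplied")

    # per-token features computed once, then shared across window offsets
    base = [_token_features(t, config) for t in tokens]
    reps = [_representation_features(t, config, models) for t in tokens]

    out = []
    n = len(tokens)
    for i in range(n):
        feats: set[str] = set()
        for d in range(-config.window, config.window + 1):
            j = i + d
            tag = f"@{d}"
            if j < 0 or j >= n:
                feats.add(f"PAD{tag}")
                continue
            feats.update(f"{f.split('=', 1)[0]}{tag}={f.split('=', 1)[1]}" for f in base[j])
            feats.update(f"{f.split('=', 1)[0]}{tag}={f.split('=', 1)[1]}" for f in reps[j])
        texts = [t.text for t in tokens]
        for m in config.word_ngram_lengths:
            feats.update(word_ngrams(texts, i, m))
        if config.use_raw_wv and models.wv is not None:
            from .wordrep import emit_raw_wv_features

            feats.update(emit_raw_wv_features(models.wv, tokens[i].text))
        out.append(FeatureVector(position=i, features=feats))
    return out
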