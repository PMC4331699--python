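"""Brown clustering: hierarchical word clustering by bigram mutual information.

Words are greedily agglomerated so as to maximize the average mutual
information between the cluster of a word and the cluster of the word that
follows it. The induction uses the classic active-set strategy: the K most
frequent words seed K singleton clusters; every further word enters as a
temporary (K+1)-th cluster and the pair of clusters whose merge costs the
least quality is merged, keeping the active set at K. A final K-1 merges
build the full binary merge tree, whose root-to-leaf bit strings provide
hierarchical word features (prefixes of the bit string at several lengths).
Complexity is O(V * K^2) quality-delta evaluations rather than the O(V^3)
of naive all-pairs agglomeration.

Quality (in bits) of a partition C is

    I(C) = sum_{c,c'} P(c,c') * log2( P(c,c') / (P(c) * P(c')) )

with P(c,c') the bigram-normalized cluster co-occurrence probability and
P(c), P(c') its left and right margins; zero-count terms contribute zero
(maximum-likelihood estimates, no smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RARE",
    "BigramCounts",
    "BrownModel",
    "collect_bigrams",
    "quality",
    "induce",
    "prefix_feature",
    "save_clusters",
    "load_clusters",
]

RARE = "<RARE>"


@dataclass
class BigramCounts:
    """Unigram and within-line bigram counts over a tokenized corpus."""

    vocabulary: dict[str, int]
    bigrams: dict[tuple[str, str], int]
    total_tokens: int


@dataclass
class BrownModel:
    """Merge-tree bit-string paths for every word, plus the partition
    quality (bits of mutual information) at the K-cluster cut."""

    K: int
    paths: dict[str, str]
    quality: float | None = None
    frequencies: dict[str, int] = field(default_factory=dict)


def collect_bigrams(
    corpus: Iterable[Sequence[str]], min_count: int = 2
) -> BigramCounts:
    """Count unigrams and bigrams (within lines/sentences only); words with
    frequency below ``min_count`` are folded into the RARE symbol."""
    raw: dict[str, int] = {}
    lines = []
    n = 0
    for line in corpus:
        line = list(line)
        lines.append(line)
        for w in line:
            raw[w] = raw.get(w, 0) + 1
            n += 1
    if n == 0:
        raise ValueError("empty corpus: no tokens to cluster")

    def canon(w: str) -> str:
        return w if raw[w] >= min_count else RARE

    vocab: dict[str, int] = {}
    bigrams: dict[tuple[str, str], int] = {}
    for line in lines:
        mapped = [canon(w) for w in line]
        for w in mapped:
            vocab[w] = vocab.get(w, 0) + 1
        for a, b in zip(mapped[:-1], mapped[1:]):
            bigrams[(a, b)] = bigrams.get((a, b), 0) + 1
    return BigramCounts(vocabulary=vocab, bigrams=bigrams, total_tokens=n)


def _quality_from_matrix(C: np.ndarray) -> float:
    """Mutual information (bits) of a cluster-level bigram count matrix."""
    total = C.sum()
    if total == 0:
        return 0.0
    P = C / total
    pl = P.sum(axis=1)
    pr = P.sum(axis=0)
    mask = P > 0
    denom = np.outer(pl, pr)
    out = np.zeros_like(P)
    out[mask] = P[mask] * np.log2(P[mask] / denom[mask])
    return float(out.sum())


def quality(partition: dict[str, int], counts: BigramCounts) -> float:
    """Partition quality: the bigram mutual information between clusters."""
    for w in counts.vocabulary:
        if w not in partition:
            raise ValueError(f"word {w!r} missing from partition")
    ids = sorted(set(partition[w] for w in counts.vocabulary))
    index = {c: i for i, c in enumerate(ids)}
    m = len(ids)
    C = np.zeros((m, m))
    for (a, b), c in counts.bigrams.items():
        C[index[partition[a]], index[partition[b]]] += c
    return _quality_from_matrix(C)


class _Node:
    __slots__ = ("words", "freq", "min_word", "left", "right")

    def __init__(self, words, freq, min_word, left=None, right=None):
        self.words = words
        self.freq = freq
        self.min_word = min_word
        self.left = left
        self.right = right


def _merged_matrix(C: np.ndarray, i: int, j: int) -> np.ndarray:
    """Collapse rows/cols i and j of C into one (placed at position i)."""
    keep = [k for k in range(C.shape[0]) if k != j]
    M = C[np.ix_(keep, keep)].copy()
    ii = keep.index(i)
    M[ii, :] = C[i, keep] + C[j, keep]
    M[:, ii] = C[keep, i] + C[keep, j]
    M[ii, ii] = C[i, i] + C[j, j] + C[i, j] + C[j, i]
    return M


def _best_merge(C: np.ndarray) -> tuple[int, int, float]:
    """The pair (i, j), i<j, whose merge yields the highest quality; ties
    broken by the smallest (i, j)."""
    m = C.shape[0]
    best = None
    for i in range(m):
        for j in range(i + 1, m):
            q = _quality_from_matrix(_merged_matrix(C, i, j))
            if best is None or q > best[2] + 1e-12:
                best = (i, j, q)
    return best


def induce(counts: BigramCounts, K: int) -> BrownModel:
    """Greedy active-set Brown clustering.

    Seeds the K most frequent words as singletons, inserts remaining words
    by descending frequency (ties lexicographic) with a least-loss merge
    after each insertion, then merges the final K clusters down to a single
    root. Bit strings read root-to-leaf with 0 assigned to the branch whose
    subtree carries the higher total frequency (ties: lexicographically
    smaller minimum word).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    vocab = counts.vocabulary
    if K > len(vocab):
        raise ValueError(f"K={K} exceeds vocabulary size {len(vocab)}")
    order = sorted(vocab, key=lambda w: (-vocab[w], w))

    # word-level bigram counts grouped by left/right word for fast insertion
    right_of: dict[str, dict[str, int]] = {}
    left_of: dict[str, dict[str, int]] = {}
    for (a, b), c in counts.bigrams.items():
        right_of.setdefault(a, {})[b] = c
        left_of.setdefault(b, {})[a] = c

    clusters: list[_Node] = []
    word_cluster: dict[str, int] = {}  # word -> index into `clusters`
    C = np.zeros((0, 0))

    def add_singleton(w: str) -> None:
        nonlocal C
        m = len(clusters)
        clusters.append(_Node([w], vocab[w], w))
        word_cluster[w] = m
        newC = np.zeros((m + 1, m + 1))
        newC[:m, :m] = C
        for b, c in right_of.get(w, {}).items():
            if b == w:
                newC[m, m] += c
            elif b in word_cluster:
                newC[m, word_cluster[b]] += c
        for a, c in left_of.get(w, {}).items():
            if a != w and a in word_cluster:
                newC[word_cluster[a], m] += c
        C = newC

    def merge(i: int, j: int) -> None:
        nonlocal C
        a, b = clusters[i], clusters[j]
        # bit order: 0 -> higher-frequency subtree (ties: smaller min word)
        if (-a.freq, a.min_word) <= (-b.freq, b.min_word):
            zero, one = a, b
        else:
            zero, one = b, a
        node = _Node(
            a.words + b.words, a.freq + b.freq, min(a.min_word, b.min_word), zero, one
        )
        C = _merged_matrix(C, i, j)
        clusters[i] = node
        clusters.pop(j)
        for idx, cl in enumerate(clusters):
            for w in cl.words:
                word_cluster[w] = idx

    for w in order[:K]:
        add_singleton(w)
    for w in order[K:]:
        add_singleton(w)
        i, j, _q = _best_merge(C)
        merge(i, j)

    model_quality = _quality_from_matrix(C)

    while len(clusters) > 1:
        i, j, _q = _best_merge(C)
        merge(i, j)
    root = clusters[0]

    # read bit paths root-to-leaf (iterative: merge trees can be deep)
    paths: dict[str, str] = {}
    stack: list[tuple[_Node, str]] = [(root, "")]
    while stack:
        node, prefix = stack.pop()
        if node.left is None:
            for w in node.words:
                paths[w] = prefix if prefix else "0"
        else:
            stack.append((node.left, prefix + "0"))
            stack.append((node.right, prefix + "1"))
    return BrownModel(K=K, paths=paths, quality=model_quality, frequencies=dict(vocab))


def prefix_feature(model: BrownModel, word: str, L: int) -> str:
    """First ``min(L, |path|)`` bits of the word's bit string; unknown words
    fall back to their lowercased form, then to the RARE symbol, then UNK."""
    if L <= 0:
        raise ValueError("prefix length must be positive")
    path = model.paths.get(word)
    if path is None:
        path = model.paths.get(word.lower())
    if path is None:
        path = model.paths.get(RARE)
    if path is None:
        return "UNK"
    return path[:L]


def save_clusters(model: BrownModel, path) -> None:
    """Write the de-facto cluster-file layout: ``bitpath<TAB>word<TAB>freq``,
    sorted by (bitpath, word) for byte-stable output."""
    rows = sorted(model.paths.items(), key=lambda kv: (kv[1], kv[0]))
    with open(path, "w", encoding="utf-8") as fh:
        for word, bits in rows:
            freq = model.frequencies.get(word, 0)
            fh.write(f"{bits}\t{word}\t{freq}\n")


def load_clusters(path) -> BrownModel:
    """Read a cluster file; extra columns beyond the third are tolerated.

    The partition quality is not stored in the file and is left as None.
    """
    paths: dict[str, str] = {}
    freqs: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"bad cluster line: {line!r}")
            bits, word = fields[0], fields[1]
            paths[word] = bits
            if len(fields) >= 3:
                try:
                    freqs[word] = int(fields[2])
                except ValueError:
                    pass
    K = len(set(paths.values()))
    return BrownModel(K=K, paths=paths, quality=None, frequencies=freqs)
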