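"""Shallow log-linear word vectors and word-vector-class (WVC) models.

Word vectors are trained with the standard negative-sampling objective of
the CBOW / skip-gram family: a log-linear model (no hidden layer) predicting
either the middle word from its averaged context (CBOW) or each context
word from the middle word (skip-gram), optimized by plain SGD with a
linearly decaying learning rate. Training is single-threaded and fully
deterministic under a fixed seed.

A WVC model discretizes the vector space: the (L2-normalized) vectors are
clustered with K-means and each word's cluster id becomes a categorical
feature, complementing the bigram-scoped Brown clusters with wider-context
information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WVConfig",
    "WordVectorModel",
    "WVCModel",
    "train_wv",
    "negative_sampling_loss",
    "negative_sampling_grad",
    "kmeans",
    "wvc_feature",
    "emit_raw_wv_features",
    "save_vectors",
    "load_vectors",
    "save_wvc",
    "load_wvc",
]


@dataclass
class WVConfig:
    dimension: int = 250
    context_window: int = 5
    mode: str = "cbow"  # or "skipgram"
    negative_samples: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    seed: int = 0
    min_count: int = 2

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if self.context_window < 1:
            raise ValueError("context_window must be >= 1")
        if self.mode not in ("cbow", "skipgram"):
            raise ValueError(f"mode must be 'cbow' or 'skipgram', got {self.mode!r}")


@dataclass
class WordVectorModel:
    vectors: dict[str, np.ndarray]
    config: WVConfig

    @property
    def dimension(self) -> int:
        return self.config.dimension


@dataclass
class WVCModel:
    C: int
    assignment: dict[str, int]
    objective_trace: list[float] = field(default_factory=list)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def negative_sampling_loss(
    u: np.ndarray, v_pos: np.ndarray, v_negs: np.ndarray
) -> float:
    """-log sigma(u.v_pos) - sum_k log sigma(-u.v_neg_k)."""
    pos = -np.log(_sigmoid(u @ v_pos))
    neg = -np.log(_sigmoid(-(v_negs @ u))).sum() if len(v_negs) else 0.0
    return float(pos + neg)


def negative_sampling_grad(
    u: np.ndarray, v_pos: np.ndarray, v_negs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients (d/du, d/dv_pos, d/dv_negs) of the loss above."""
    g_pos = _sigmoid(u @ v_pos) - 1.0  # scalar
    g_negs = _sigmoid(v_negs @ u) if len(v_negs) else np.zeros(0)
    du = g_pos * v_pos + (g_negs[:, None] * v_negs).sum(axis=0)
    dvp = g_pos * u
    dvn = g_negs[:, None] * u
    return du, dvp, dvn


def _build_vocab(corpus: Iterable[Sequence[str]], min_count: int):
    counts: dict[str, int] = {}
    lines: list[list[str]] = []
    for line in corpus:
        line = list(line)
        lines.append(line)
        for w in line:
            counts[w] = counts.get(w, 0) + 1
    words = sorted(
        (w for w, c in counts.items() if c >= min_count),
        key=lambda w: (-counts[w], w),
    )
    if not words:
        raise ValueError("empty vocabulary after min_count filtering")
    index = {w: i for i, w in enumerate(words)}
    # drop under-threshold words from the stream entirely
    stream = [[index[w] for w in line if w in index] for line in lines]
    freqs = np.array([counts[w] for w in words], dtype=float)
    return words, index, stream, freqs


def train_wv(corpus: Iterable[Sequence[str]], config: WVConfig) -> WordVectorModel:
    """SGD training of the negative-sampling objective; returns the
    input-side vectors. Deterministic for a fixed config.seed."""
    words, _index, stream, freqs = _build_vocab(corpus, config.min_count)
    V, d = len(words), config.dimension
    rng = np.random.RandomState(config.seed)
    U = (rng.rand(V, d) - 0.5) / d  # input-side
    W = np.zeros((V, d))  # output-side

    noise = freqs**0.75
    noise /= noise.sum()
    cum_noise = np.cumsum(noise)

    total_words = sum(len(s) for s in stream) * config.epochs
    processed = 0
    k = config.negative_samples
    lr0 = config.learning_rate

    for _epoch in range(config.epochs):
        for sent in stream:
            for t, center in enumerate(sent):
                processed += 1
                lr = lr0 * max(1e-4, 1.0 - processed / (total_words + 1))
                b = rng.randint(1, config.context_window + 1)
                lo, hi = max(0, t - b), min(len(sent), t + b + 1)
                context = [sent[j] for j in range(lo, hi) if j != t]
                if not context:
                    continue
                if config.mode == "skipgram":
                    for c in context:
                        negs = np.searchsorted(cum_noise, rng.rand(k))
                        u = U[center]
                        du, dvp, dvn = negative_sampling_grad(u, W[c], W[negs])
                        U[center] = u - lr * du
                        W[c] -= lr * dvp
                        np.subtract.at(W, negs, lr * dvn)
                else:  # cbow: average context inputs predicts the center
                    h = U[context].mean(axis=0)
                    negs = np.searchsorted(cum_noise, rng.rand(k))
                    dh, dvp, dvn = negative_sampling_grad(h, W[center], W[negs])
                    W[center] -= lr * dvp
                    np.subtract.at(W, negs, lr * dvn)
                    np.add.at(U, context, -lr * dh / len(context))

    vectors = {w: U[i].copy() for i, w in enumerate(words)}
    return WordVectorModel(vectors=vectors, config=config)


def _kmeans_pp_init(X: np.ndarray, C: int, rng: np.random.RandomState) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((C, X.shape[1]))
    centers[0] = X[rng.randint(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for c in range(1, C):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        idx = np.searchsorted(np.cumsum(probs), rng.rand())
        centers[c] = X[min(idx, n - 1)]
        d2 = np.minimum(d2, ((X - centers[c]) ** 2).sum(axis=1))
    return centers


def kmeans(model: WordVectorModel, C: int, seed: int = 0) -> WVCModel:
    """Lloyd's K-means with k-means++ seeding over L2-normalized vectors.

    Iterates to an assignment fixpoint (at most 100 iterations); empty
    clusters are re-seeded with the point farthest from its centroid. The
    within-cluster sum of squares is recorded per iteration and is
    non-increasing.
    """
    words = sorted(model.vectors)
    if C > len(words):
        raise ValueError(f"C={C} exceeds vocabulary size {len(words)}")
    X = np.stack([model.vectors[w] for w in words])
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    X = X / norms

    rng = np.random.RandomState(seed)
    centers = _kmeans_pp_init(X, C, rng)
    assign = np.full(len(words), -1)
    trace: list[float] = []
    for _it in range(100):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(len(words)), new_assign].sum()))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(C):
            mask = assign == c
            if mask.any():
                centers[c] = X[mask].mean(axis=0)
            else:  # re-seed with the globally farthest point
                far = d2[np.arange(len(words)), assign].argmax()
                centers[c] = X[far]
                assign[far] = c
    # dense relabeling in order of first appearance for stable ids
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for w, a in zip(words, assign):
        if int(a) not in relabel:
            relabel[int(a)] = len(relabel)
        assignment[w] = relabel[int(a)]
    return WVCModel(C=C, assignment=assignment, objective_trace=trace)


def wvc_feature(model: WVCModel, word: str, tag: str) -> str:
    """``tag=<class id>`` with lowercase fallback, else ``tag=UNK``."""
    cid = model.assignment.get(word)
    if cid is None:
        cid = model.assignment.get(word.lower())
    if cid is None:
        return f"{tag}=UNK"
    return f"{tag}={cid}"


def emit_raw_wv_features(model: WordVectorModel, word: str) -> list[str]:
    """Per-dimension continuous features ``WV<d>=<value>``; empty for
    unseen words. Off by default in FeatureConfig (can hurt performance)."""
    vec = model.vectors.get(word)
    if vec is None:
        vec = model.vectors.get(word.lower())
    if vec is None:
        return []
    return [f"WV{i}={v:.6f}" for i, v in enumerate(vec)]


def save_vectors(model: WordVectorModel, path) -> None:
    words = sorted(model.vectors)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(words)} {model.dimension}\n")
        for w in words:
            vals = " ".join(repr(float(v)) for v in model.vectors[w])
            fh.write(f"{w} {vals}\n")


def load_vectors(path) -> WordVectorModel:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("missing 'V d' header line")
        _v, d = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise ValueError(f"bad vector line for {parts[0]!r}")
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    cfg = WVConfig(dimension=d)
    return WordVectorModel(vectors=vectors, config=cfg)


def save_wvc(model: WVCModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for w in sorted(model.assignment):
            fh.write(f"{w}\t{model.assignment[w]}\n")


def load_wvc(path) -> WVCModel:
    assignment: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            w, cid = line.split("\t")
            assignment[w] = int(cid)
    return WVCModel(C=len(set(assignment.values())), assignment=assignment)
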