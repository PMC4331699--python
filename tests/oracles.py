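"""Independent oracle helpers shared across test modules."""

from __future__ import annotations

import itertools

import numpy as np

from chemner import crf
from chemner.features import FeatureVector


def random_crf_model(rng, labels=("O", "B-C", "I-C"), n_feats=6, scale=1.0):
    labels = list(labels)
    feats = [f"f{i}" for i in range(n_feats)]
    return crf.CRFModel(
        labels=labels,
        feature_index={k: i for i, k in enumerate(feats)},
        w_emit=rng.randn(n_feats, len(labels)) * scale,
        w_trans=rng.randn(len(labels) + 1, len(labels) + 1, len(labels)) * scale,
    )


def random_feature_vectors(rng, model, T, per_pos=2):
    keys = list(model.feature_index)
    return [
        FeatureVector(t, set(rng.choice(keys, size=per_pos, replace=False)))
        for t in range(T)
    ]


def enumerate_sequences(model, fvs):
    """Brute-force distribution over all |L|^T label sequences.

    Returns (sequences, scores, logZ): the independent oracle for the
    partition function, Viterbi argmax and marginals.
    """
    T = len(fvs)
    seqs = list(itertools.product(model.labels, repeat=T))
    scores = np.array([crf.score(model, fvs, list(s)) for s in seqs])
    m = scores.max()
    logZ = float(np.log(np.exp(scores - m).sum()) + m)
    return seqs, scores, logZ


def brute_force_marginals(model, fvs):
    seqs, scores, logZ = enumerate_sequences(model, fvs)
    T, L = len(fvs), len(model.labels)
    M = np.zeros((T, L))
    for s, sc in zip(seqs, scores):
        p = np.exp(sc - logZ)
        for t, lab in enumerate(s):
            M[t, model.labels.index(lab)] += p
    return M


def legal_random_bio(rng, T, etype="C"):
    """A random label sequence respecting BIO legality."""
    labs = []
    prev = "O"
    for _ in range(T):
        choices = ["O", f"B-{etype}"]
        if prev in (f"B-{etype}", f"I-{etype}"):
            choices.append(f"I-{etype}")
        prev = choices[rng.randint(len(choices))]
        labs.append(prev)
    return labs
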