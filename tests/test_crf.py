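"""Second-order CRF: exact inference vs enumeration, training, decoding."""

import numpy as np
import pytest

from chemner import crf
from chemner.features import FeatureVector

from oracles import (
    brute_force_marginals,
    enumerate_sequences,
    legal_random_bio,
    random_crf_model,
    random_feature_vectors,
)


def test_score_zero_weights(rng):
    m = random_crf_model(rng, scale=0.0)
    fvs = random_feature_vectors(rng, m, 4)
    assert crf.score(m, fvs, ["O", "B-C", "I-C", "O"]) == 0.0


def test_score_linear_in_weights(rng):
    m = random_crf_model(rng)
    fvs = random_feature_vectors(rng, m, 5)
    labs = legal_random_bio(rng, 5)
    s1 = crf.score(m, fvs, labs)
    m.w_emit = m.w_emit * 2
    m.w_trans = m.w_trans * 2
    assert crf.score(m, fvs, labs) == pytest.approx(2 * s1)


def test_score_unknown_label_errors(rng):
    m = random_crf_model(rng)
    fvs = random_feature_vectors(rng, m, 2)
    with pytest.raises(ValueError, match="unknown label"):
        crf.score(m, fvs, ["O", "B-X"])


def test_sequence_probabilities_sum_to_one(rng):
    for _ in range(5):
        m = random_crf_model(rng)
        fvs = random_feature_vectors(rng, m, int(rng.randint(1, 6)))
        _seqs, scores, logZ = enumerate_sequences(m, fvs)
        assert np.exp(scores - logZ).sum() == pytest.approx(1.0)
        assert crf.log_partition(m, fvs) == pytest.approx(logZ, abs=1e-9)


def test_viterbi_matches_enumeration(rng):
    for _ in range(30):
        m = random_crf_model(rng)
        T = int(rng.randint(1, 7))
        fvs = random_feature_vectors(rng, m, T)
        seqs, scores, logZ = enumerate_sequences(m, fvs)
        labs, lp = crf.viterbi(m, fvs, constrain_bio=False)
        best = int(np.argmax(scores))
        assert labs == list(seqs[best])
        assert lp == pytest.approx(scores[best] - logZ, abs=1e-9)


def test_viterbi_single_token_strong_o():
    labels = ["O", "B-C", "I-C"]
    m = crf.CRFModel(
        labels=labels,
        feature_index={"f": 0},
        w_emit=np.array([[5.0, 0.0, 0.0]]),
        w_trans=np.zeros((4, 4, 3)),
    )
    labs, _ = crf.viterbi(m, [FeatureVector(0, {"f"})])
    assert labs == ["O"]


def test_viterbi_empty_sequence(rng):
    m = random_crf_model(rng)
    assert crf.viterbi(m, []) == ([], 0.0)


def test_decoded_score_at_least_gold(rng):
    for _ in range(10):
        m = random_crf_model(rng)
        T = int(rng.randint(1, 7))
        fvs = random_feature_vectors(rng, m, T)
        gold = legal_random_bio(rng, T)
        labs, _ = crf.viterbi(m, fvs, constrain_bio=False)
        assert crf.score(m, fvs, labs) >= crf.score(m, fvs, gold) - 1e-9


def test_marginals_match_enumeration(rng):
    for _ in range(15):
        m = random_crf_model(rng)
        T = int(rng.randint(1, 6))
        fvs = random_feature_vectors(rng, m, T)
        M = crf.marginals(m, fvs)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(M, brute_force_marginals(m, fvs), atol=1e-9)


def test_uniform_weights_give_uniform_posteriors(rng):
    m = random_crf_model(rng, scale=0.0)
    fvs = random_feature_vectors(rng, m, 4)
    M = crf.marginals(m, fvs)
    assert np.allclose(M, 1.0 / 3.0)


def test_decoding_invariant_to_constant_shift_of_position(rng):
    """Adding a constant to every label's weight for one position's features
    shifts all sequence scores equally and leaves the argmax unchanged."""
    m = random_crf_model(rng)
    fvs = [FeatureVector(t, {f"f{t}"}) for t in range(4)]
    m.feature_index = {f"f{t}": t for t in range(4)}
    m.w_emit = np.asarray(np.random.RandomState(5).randn(4, 3))
    labs1, _ = crf.viterbi(m, fvs, constrain_bio=False)
    m2 = crf.CRFModel(
        labels=m.labels,
        feature_index=m.feature_index,
        w_emit=m.w_emit + np.array([[7.0, 7.0, 7.0], [0, 0, 0], [0, 0, 0], [0, 0, 0]]),
        w_trans=m.w_trans,
    )
    labs2, _ = crf.viterbi(m2, fvs, constrain_bio=False)
    assert labs1 == labs2


def test_bio_constraint_forbids_orphan_inside(rng):
    """With the structural constraint no decode emits I-X after O/BOS."""
    for _ in range(20):
        m = random_crf_model(rng, scale=3.0)
        fvs = random_feature_vectors(rng, m, int(rng.randint(1, 7)))
        labs, _ = crf.viterbi(m, fvs, constrain_bio=True)
        prev = "O"
        for lab in labs:
            if lab == "I-C":
                assert prev in ("B-C", "I-C")
            prev = lab


def test_forward_backward_partition_agreement(rng):
    """The backward recursion reproduces the forward partition value."""
    from chemner.crf import _backward, _forward
    from scipy.special import logsumexp

    for _ in range(10):
        m = random_crf_model(rng)
        T = int(rng.randint(2, 7))
        fvs = random_feature_vectors(rng, m, T)
        E = m.emissions(fvs)
        a0, _alphas, logZ = _forward(E, m.w_trans, m.bos)
        b0, _betas = _backward(E, m.w_trans, m.bos)
        assert logsumexp(a0 + b0) == pytest.approx(logZ, abs=1e-9)


def test_labeled_sequence_validation(rng):
    m = random_crf_model(rng)
    fvs = random_feature_vectors(rng, m, 2)
    with pytest.raises(ValueError, match="illegal BIO"):
        crf.LabeledSequence(fvs, ["O", "I-C"])
    with pytest.raises(ValueError, match="length|vectors"):
        crf.LabeledSequence(fvs, ["O"])


def test_training_gradient_matches_finite_differences(rng):
    feats = [f"f{i}" for i in range(5)]
    data = []
    for _ in range(6):
        T = int(rng.randint(1, 6))
        fvs = [
            FeatureVector(t, set(rng.choice(feats, 2, replace=False)))
            for t in range(T)
        ]
        data.append(crf.LabeledSequence(fvs, legal_random_bio(rng, T)))
    obj, labels, fi = crf.make_objective(data, sigma=1.0)
    n = len(fi) * len(labels) + (len(labels) + 1) ** 2 * len(labels)
    w = rng.randn(n) * 0.3
    _f, g = obj(w)
    eps = 1e-6
    g_num = np.zeros(n)
    for i in range(n):
        wp, wm = w.copy(), w.copy()
        wp[i] += eps
        wm[i] -= eps
        g_num[i] = (obj(wp)[0] - obj(wm)[0]) / (2 * eps)
    denom = np.maximum(1e-6, np.abs(g) + np.abs(g_num))
    assert (np.abs(g - g_num) / denom).max() < 1e-6


def test_training_on_separable_data_reaches_perfect_accuracy(rng):
    """A single indicator feature separates entities from outside tokens:
    training must fit the training set exactly."""
    data = []
    for _ in range(20):
        T = int(rng.randint(2, 8))
        labs = legal_random_bio(rng, T)
        fvs = [
            FeatureVector(
                t, {{"O": "plain", "B-C": "chem-b", "I-C": "chem-i"}[labs[t]]}
            )
            for t in range(T)
        ]
        data.append(crf.LabeledSequence(fvs, labs))
    model = crf.train(data, sigma=10.0, max_iter=200)
    correct = total = 0
    for seq in data:
        pred, _ = crf.viterbi(model, seq.feature_vectors)
        correct += sum(p == g for p, g in zip(pred, seq.labels))
        total += len(seq.labels)
    assert correct == total
    # accepted-step objective trace is monotone non-increasing
    trace = model.training_log
    assert all(b <= a + 1e-6 for a, b in zip(trace, trace[1:]))


def test_empty_training_data_errors():
    with pytest.raises(ValueError, match="no training sequences"):
        crf.train([])


def test_model_serialization_roundtrip(rng, tmp_path):
    feats = [f"f{i}" for i in range(4)]
    data = [
        crf.LabeledSequence(
            [FeatureVector(t, {feats[t % 4]}) for t in range(3)],
            ["O", "B-C", "I-C"],
        )
    ]
    model = crf.train(data, max_iter=20)
    p = tmp_path / "model.tsv"
    crf.save_model(model, p)
    loaded = crf.load_model(p)
    assert loaded.labels == model.labels
    assert loaded.feature_index == model.feature_index
    assert np.allclose(loaded.w_emit, model.w_emit)
    assert np.allclose(loaded.w_trans, model.w_trans)
    # load . save = identity
    p2 = tmp_path / "model2.tsv"
    crf.save_model(loaded, p2)
    assert p.read_bytes() == p2.read_bytes()
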