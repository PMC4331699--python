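"""Word-vector training and K-means word-vector classes.

scikit-learn's KMeans serves as an independent oracle for the clustering
objective; gradients are checked by central finite differences; vector
semantics are checked by latent-class recovery on generated corpora.
"""

import numpy as np
import pytest

from chemner.synthetic import gen_class_lm_corpus
from chemner.wordrep import (
    WVCModel,
    WVConfig,
    WordVectorModel,
    emit_raw_wv_features,
    kmeans,
    load_vectors,
    load_wvc,
    negative_sampling_grad,
    negative_sampling_loss,
    save_vectors,
    save_wvc,
    train_wv,
    wvc_feature,
)


def test_config_validation():
    with pytest.raises(ValueError):
        WVConfig(dimension=1)
    with pytest.raises(ValueError):
        WVConfig(mode="glove")


def test_negative_sampling_gradient_matches_finite_differences():
    rng = np.random.RandomState(4)
    d, k = 7, 4
    u, vp = rng.randn(d), rng.randn(d)
    vn = rng.randn(k, d)
    du, dvp, dvn = negative_sampling_grad(u, vp, vn)
    eps = 1e-6

    def fd(f, x):
        g = np.zeros_like(x)
        flat = x.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = f()
            flat[i] = orig - eps
            lo = f()
            flat[i] = orig
            g.ravel()[i] = (hi - lo) / (2 * eps)
        return g

    gu = fd(lambda: negative_sampling_loss(u, vp, vn), u)
    gvp = fd(lambda: negative_sampling_loss(u, vp, vn), vp)
    gvn = fd(lambda: negative_sampling_loss(u, vp, vn), vn)
    for a, b in ((du, gu), (dvp, gvp), (dvn, gvn)):
        assert np.abs(a - b).max() / max(1e-8, np.abs(b).max()) < 1e-5


def test_requested_dimension_is_respected():
    lines, _ = gen_class_lm_corpus(1, 2, 4, 600)
    model = train_wv(lines, WVConfig(dimension=10, epochs=1, min_count=1))
    assert all(v.shape == (10,) for v in model.vectors.values())


def test_empty_vocabulary_errors():
    with pytest.raises(ValueError, match="empty vocabulary"):
        train_wv([["a"], ["b"]], WVConfig(dimension=5, min_count=5))


def test_interchangeable_words_end_up_close():
    """Words with identical context distributions (same latent class) have
    higher mutual cosine than the average to other words."""
    lines, w2c = gen_class_lm_corpus(21, 2, 3, 8000, switch_noise=0.02)
    model = train_wv(
        lines, WVConfig(dimension=16, epochs=4, seed=3, min_count=1, mode="skipgram")
    )
    words = sorted(model.vectors)
    X = np.stack([model.vectors[w] for w in words])
    X = X / np.linalg.norm(X, axis=1, keepdims=True)
    cos = X @ X.T
    same = [
        cos[i, j]
        for i in range(len(words))
        for j in range(len(words))
        if i < j and w2c[words[i]] == w2c[words[j]]
    ]
    diff = [
        cos[i, j]
        for i in range(len(words))
        for j in range(len(words))
        if i < j and w2c[words[i]] != w2c[words[j]]
    ]
    assert np.mean(same) > np.mean(diff)


def test_training_deterministic_under_seed():
    lines, _ = gen_class_lm_corpus(23, 2, 3, 1500)
    cfg = WVConfig(dimension=8, epochs=2, seed=11, min_count=1)
    m1 = train_wv(lines, cfg)
    m2 = train_wv(lines, WVConfig(dimension=8, epochs=2, seed=11, min_count=1))
    for w in m1.vectors:
        assert np.array_equal(m1.vectors[w], m2.vectors[w])


def _cloud_model(rng, C=3, per=8, d=6, sep=10.0):
    vectors = {}
    labels = {}
    centers = rng.randn(C, d) * sep
    for c in range(C):
        for i in range(per):
            w = f"k{c}_{i}"
            vectors[w] = centers[c] + rng.randn(d)
            labels[w] = c
    return WordVectorModel(vectors, WVConfig(dimension=d)), labels


def test_kmeans_recovers_separated_clouds():
    rng = np.random.RandomState(6)
    model, labels = _cloud_model(rng)
    wvc = kmeans(model, 3, seed=0)
    # same generator class <=> same cluster id (up to permutation)
    mapping = {}
    for w, cid in wvc.assignment.items():
        mapping.setdefault(labels[w], set()).add(cid)
    assert all(len(v) == 1 for v in mapping.values())
    assert len({next(iter(v)) for v in mapping.values()}) == 3


def test_kmeans_objective_monotone():
    rng = np.random.RandomState(7)
    model, _ = _cloud_model(rng, C=4, per=10, d=5, sep=3.0)
    wvc = kmeans(model, 4, seed=1)
    trace = wvc.objective_trace
    assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))


def test_kmeans_matches_sklearn_on_separated_clouds():
    """On well-separated clouds both Lloyd implementations reach the global
    optimum: scikit-learn is the independent oracle for the objective."""
    sklearn_cluster = pytest.importorskip("sklearn.cluster")
    rng = np.random.RandomState(12)
    model, _ = _cloud_model(rng, C=3, per=12, d=6, sep=10.0)
    wvc = kmeans(model, 3, seed=1)
    words = sorted(model.vectors)
    X = np.stack([model.vectors[w] for w in words])
    X = X / np.linalg.norm(X, axis=1, keepdims=True)
    km = sklearn_cluster.KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
    assert wvc.objective_trace[-1] == pytest.approx(km.inertia_, rel=1e-6)


def test_kmeans_c_equals_vocab_gives_zero_objective():
    rng = np.random.RandomState(8)
    model, _ = _cloud_model(rng, C=2, per=3)
    wvc = kmeans(model, 6, seed=0)
    assert wvc.objective_trace[-1] == pytest.approx(0.0, abs=1e-12)
    assert len(set(wvc.assignment.values())) == 6


def test_kmeans_c_larger_than_vocab_errors():
    rng = np.random.RandomState(9)
    model, _ = _cloud_model(rng, C=2, per=2)
    with pytest.raises(ValueError, match="exceeds"):
        kmeans(model, 10, seed=0)


def test_wvc_feature_fallbacks():
    wvc = WVCModel(C=3, assignment={"edta": 2, "Acid": 1})
    assert wvc_feature(wvc, "edta", "WVC500") == "WVC500=2"
    assert wvc_feature(wvc, "EDTA", "WVC500") == "WVC500=2"  # lowercase fallback
    assert wvc_feature(wvc, "unknown", "WVC500") == "WVC500=UNK"


def test_raw_wv_features():
    model = WordVectorModel(
        {"edta": np.arange(4, dtype=float)}, WVConfig(dimension=4)
    )
    feats = emit_raw_wv_features(model, "edta")
    assert len(feats) == 4
    assert feats[0] == "WV0=0.000000"
    assert emit_raw_wv_features(model, "nope") == []


def test_vector_and_wvc_file_roundtrip(tmp_path):
    lines, _ = gen_class_lm_corpus(29, 2, 3, 800)
    model = train_wv(lines, WVConfig(dimension=6, epochs=1, min_count=1))
    vp = tmp_path / "vectors.txt"
    save_vectors(model, vp)
    loaded = load_vectors(vp)
    assert vp.read_text().splitlines()[0] == f"{len(model.vectors)} 6"
    for w, v in model.vectors.items():
        assert np.array_equal(loaded.vectors[w], v)

    wvc = kmeans(model, 2, seed=5)
    wp = tmp_path / "wvc.tsv"
    save_wvc(wvc, wp)
    assert load_wvc(wp).assignment == wvc.assignment


def test_wvc_files_byte_identical_across_runs(tmp_path):
    lines, _ = gen_class_lm_corpus(31, 3, 3, 1200)
    cfg = WVConfig(dimension=8, epochs=2, seed=2, min_count=1)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    save_wvc(kmeans(train_wv(lines, cfg), 3, seed=9), p1)
    save_wvc(kmeans(train_wv(lines, cfg), 3, seed=9), p2)
    assert p1.read_bytes() == p2.read_bytes()
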