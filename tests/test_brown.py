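"""Brown clustering against hand-counted and exhaustive-search oracles."""

import itertools
import math

import numpy as np
import pytest

from chemner.brown import (
    RARE,
    BigramCounts,
    collect_bigrams,
    induce,
    load_clusters,
    prefix_feature,
    quality,
    save_clusters,
)
from chemner.synthetic import gen_class_lm_corpus


def hand_quality(partition, counts):
    """Independent oracle: direct enumeration of the bigram table and the
    mutual-information sum (pure Python, base-2 logs)."""
    N = sum(counts.bigrams.values())
    joint = {}
    for (a, b), c in counts.bigrams.items():
        k = (partition[a], partition[b])
        joint[k] = joint.get(k, 0) + c
    left, right = {}, {}
    for (ca, cb), c in joint.items():
        left[ca] = left.get(ca, 0) + c
        right[cb] = right.get(cb, 0) + c
    I = 0.0
    for (ca, cb), c in joint.items():
        p = c / N
        I += p * math.log2(p / ((left[ca] / N) * (right[cb] / N)))
    return I


def all_partitions(words, k):
    """Every partition of `words` into exactly k non-empty clusters
    (restricted-growth strings)."""

    def rec(i, maxid, assign):
        if i == len(words):
            if maxid + 1 == k:
                yield dict(zip(words, assign))
            return
        for c in range(min(maxid + 1, k - 1) + 1):
            yield from rec(i + 1, max(maxid, c), assign + [c])

    yield from rec(1, 0, [0]) if words else iter(())


def test_collect_bigrams_counts():
    counts = collect_bigrams([["a", "b", "a", "b"]], min_count=1)
    assert counts.vocabulary == {"a": 2, "b": 2}
    assert counts.bigrams == {("a", "b"): 2, ("b", "a"): 1}
    assert counts.total_tokens == 4


def test_collect_bigrams_rare_folding():
    counts = collect_bigrams([["a", "a", "b"]], min_count=2)
    assert counts.vocabulary == {"a": 2, RARE: 1}
    assert ("a", RARE) in counts.bigrams


def test_collect_bigrams_line_boundary():
    counts = collect_bigrams([["a", "b"], ["c", "d"]], min_count=1)
    assert ("b", "c") not in counts.bigrams


def test_collect_bigrams_empty_corpus():
    with pytest.raises(ValueError, match="empty"):
        collect_bigrams([], min_count=1)


def test_quality_single_cluster_is_zero():
    counts = collect_bigrams([["a", "b", "a", "b", "a"]], min_count=1)
    assert quality({"a": 0, "b": 0}, counts) == pytest.approx(0.0)


def test_quality_matches_hand_count():
    counts = collect_bigrams([["a", "b", "a", "b", "a", "b"]], min_count=1)
    part = {"a": 0, "b": 1}
    assert quality(part, counts) == pytest.approx(hand_quality(part, counts))
    # alternating corpus: 5 bigrams, ab x3, ba x2 -> strong MI
    assert quality(part, counts) > 0.9


def test_quality_invariant_under_relabeling():
    lines, _ = gen_class_lm_corpus(3, 2, 3, 400)
    counts = collect_bigrams(lines, min_count=1)
    words = sorted(counts.vocabulary)
    part = {w: i % 3 for i, w in enumerate(words)}
    relabeled = {w: (c + 7) * 13 for w, c in part.items()}
    assert quality(part, counts) == pytest.approx(quality(relabeled, counts))


def test_quality_missing_word_errors():
    counts = collect_bigrams([["a", "b"]], min_count=1)
    with pytest.raises(ValueError, match="missing"):
        quality({"a": 0}, counts)


def test_quality_nonnegative_and_bounded_by_entropy():
    rng = np.random.RandomState(0)
    lines, _ = gen_class_lm_corpus(5, 3, 3, 600)
    counts = collect_bigrams(lines, min_count=1)
    words = sorted(counts.vocabulary)
    for _ in range(10):
        part = {w: int(rng.randint(3)) for w in words}
        q = quality(part, counts)
        assert q >= -1e-12
        # entropy of cluster marginals bounds mutual information
        N = sum(counts.bigrams.values())
        left = {}
        for (a, _b), c in counts.bigrams.items():
            left[part[a]] = left.get(part[a], 0) + c
        H = -sum(c / N * math.log2(c / N) for c in left.values())
        assert q <= H + 1e-9


def test_induce_k_larger_than_vocab_errors():
    counts = collect_bigrams([["a", "b"]], min_count=1)
    with pytest.raises(ValueError, match="exceeds"):
        induce(counts, 5)


def test_induce_vocab_equals_k():
    counts = collect_bigrams([["a", "b", "c", "a", "b", "c"]], min_count=1)
    model = induce(counts, 3)
    paths = {model.paths[w] for w in "abc"}
    assert len(paths) == 3  # all singletons, distinct leaves
    assert model.quality == pytest.approx(
        quality({"a": 0, "b": 1, "c": 2}, counts)
    )


def test_induce_recovers_two_class_bigram_lm():
    """On an alternating 2-class corpus the K=2 cut equals the generating
    classes — checked against exhaustive search over all 2-partitions."""
    lines, w2c = gen_class_lm_corpus(7, 2, 4, 3000, switch_noise=0.0)
    counts = collect_bigrams(lines, min_count=1)
    model = induce(counts, 2)
    # partition at the 1-bit cut
    cut = {w: model.paths[w][0] for w in counts.vocabulary}
    groups = {}
    for w, b in cut.items():
        groups.setdefault(b, set()).add(w)
    recovered = {frozenset(g) for g in groups.values()}
    expected = {
        frozenset(w for w in counts.vocabulary if w2c[w] == c) for c in (0, 1)
    }
    assert recovered == expected
    # exhaustive oracle: no 2-partition scores higher
    words = sorted(counts.vocabulary)
    best = max(hand_quality(p, counts) for p in all_partitions(words, 2))
    assert model.quality == pytest.approx(best, abs=1e-9)


@pytest.mark.parametrize("k", [2, 3])
def test_greedy_quality_bounded_by_exhaustive_max(k):
    lines, _ = gen_class_lm_corpus(11, 3, 2, 500, switch_noise=0.15)
    counts = collect_bigrams(lines, min_count=1)
    words = sorted(counts.vocabulary)
    assert len(words) <= 8
    model = induce(counts, k)
    best = max(hand_quality(p, counts) for p in all_partitions(words, k))
    assert model.quality <= best + 1e-9


def test_final_merges_monotone_nonincreasing():
    """Quality at coarser cuts never exceeds quality at the K cut."""
    lines, _ = gen_class_lm_corpus(13, 3, 3, 2000)
    counts = collect_bigrams(lines, min_count=1)
    model = induce(counts, 4)
    words = sorted(counts.vocabulary)
    prev = model.quality
    for bits in (2, 1):
        part = {w: model.paths[w][:bits] for w in words}
        ids = {p: i for i, p in enumerate(sorted(set(part.values())))}
        q = quality({w: ids[p] for w, p in part.items()}, counts)
        assert q <= prev + 1e-9
        prev = q


def test_determinism_byte_identical_path_tables(tmp_path):
    lines, _ = gen_class_lm_corpus(17, 3, 4, 4000)
    counts = collect_bigrams(lines, min_count=1)
    f1, f2 = tmp_path / "c1.tsv", tmp_path / "c2.tsv"
    save_clusters(induce(counts, 4), f1)
    save_clusters(induce(collect_bigrams(lines, min_count=1), 4), f2)
    assert f1.read_bytes() == f2.read_bytes()


def test_prefix_feature_rules():
    model = induce(collect_bigrams([["A", "b", "A", "b", "c", "A"]], min_count=1), 2)
    model.paths = {"A": "110101110", "b": "10", RARE: "0"}
    assert prefix_feature(model, "A", 4) == "1101"
    assert prefix_feature(model, "b", 6) == "10"
    assert prefix_feature(model, "B", 6) == "10"  # lowercase fallback
    # unknown word falls back to RARE's path
    assert prefix_feature(model, "zzz", 4) == "0"
    model.paths.pop(RARE)
    assert prefix_feature(model, "zzz", 4) == "UNK"


def test_cluster_file_roundtrip(tmp_path):
    lines, _ = gen_class_lm_corpus(19, 2, 3, 1000)
    model = induce(collect_bigrams(lines, min_count=1), 2)
    p = tmp_path / "clusters.tsv"
    save_clusters(model, p)
    loaded = load_clusters(p)
    assert loaded.paths == model.paths
    assert loaded.K == len(set(model.paths.values()))
    # reader tolerates extra columns
    p2 = tmp_path / "extra.tsv"
    p2.write_text("01\tword\t5\textra\n", encoding="utf-8")
    assert load_clusters(p2).paths == {"word": "01"}
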