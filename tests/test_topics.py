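"""Embedding, density clustering, class-based key terms, topic merging."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import rand_score

from switchscope.topics import cluster_topics, embed, merge, top_terms, topic_model


def test_embedding_is_deterministic_and_separates_disjoint_vocab():
    texts = ["spotting bleeding periods", "insurance coverage denied"]
    a, b = embed(texts), embed(texts)
    assert np.array_equal(a, b)
    assert float(a[0] @ a[1]) == 0.0  # disjoint vocabularies -> orthogonal


def test_embed_rejects_empty_list_and_unknown_backend():
    with pytest.raises(ValueError, match="non-empty"):
        embed([])
    with pytest.raises(ValueError, match="backend"):
        embed(["a"], backend="word2vec")


def test_backend_plugin_flows_through_clustering():
    rng = np.random.default_rng(0)
    texts = [f"text {i}" for i in range(30)]
    custom = lambda ts: rng.normal(size=(len(ts), 6))
    result = cluster_topics(embed(texts, backend=custom), min_cluster_size=5, seed=0)
    assert len(result.assignments) == 30


def _blobs(seed, n_per=20, sep=50.0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, size=(3, 8))
    X = np.vstack([c + rng.normal(0, 1.0, size=(n_per, 8)) for c in centers])
    return X, np.repeat([0, 1, 2], n_per)


def test_planted_blob_partition_recovered_across_seeds():
    """Three well-separated blobs: exactly 3 topics, >=95% co-membership."""
    for seed in range(10):
        X, truth = _blobs(seed)
        result = cluster_topics(X, min_cluster_size=10, seed=seed)
        assert result.n_topics == 3
        assert rand_score(truth, result.assignments.to_numpy()) >= 0.95


def test_identical_vectors_form_single_topic():
    X = np.ones((20, 4))
    result = cluster_topics(X, min_cluster_size=5, seed=0)
    assert result.n_topics == 1
    assert (result.assignments == 1).all()


def test_q_rows_sum_to_one_and_noise_gets_reserved_topic():
    X, _ = _blobs(3)
    X = np.vstack([X, np.full((1, 8), 500.0)])  # a far outlier
    result = cluster_topics(X, min_cluster_size=10, seed=3)
    assert np.allclose(result.q.sum(axis=1), 1.0, atol=1e-9)
    outlier_topic = int(result.assignments.iloc[-1])
    if outlier_topic == 0:  # noise label carries all its weight
        assert result.q.iloc[-1, 0] == 1.0


def test_too_few_vectors_rejected():
    with pytest.raises(ValueError, match="at least"):
        cluster_topics(np.eye(4), seed=0)


def test_key_term_weights_match_stated_formula():
    texts = ["spotting bleeding", "spotting pain", "insurance coverage", "insurance pain"]
    assignments = [1, 1, 2, 2]
    terms = top_terms(texts, assignments, k=5)
    # hand evaluation: freq(t,c) * log(1 + n_topics / n_topics_containing_t)
    idf_exclusive = np.log1p(2 / 1)
    idf_shared = np.log1p(2 / 2)
    t1 = dict(terms[1])
    assert t1["spotting"] == pytest.approx(2 * idf_exclusive)
    assert t1["bleeding"] == pytest.approx(1 * idf_exclusive)
    assert t1["pain"] == pytest.approx(1 * idf_shared)
    # exclusive term outranks the shared term within its topic
    assert [w for _, w in terms[1]] == sorted((w for _, w in terms[1]), reverse=True)
    assert t1["spotting"] > t1["pain"]


def test_key_terms_invariant_to_text_order_within_topic():
    texts = ["aa bb", "bb cc", "xx yy", "yy zz"]
    assignments = [1, 1, 2, 2]
    swapped = top_terms(texts[::-1], assignments[::-1], k=4)
    assert top_terms(texts, assignments, k=4) == swapped


def test_top_terms_rejects_bad_k():
    with pytest.raises(ValueError, match="k must be"):
        top_terms(["a"], [1], k=0)


@pytest.fixture(scope="module")
def clustered_blobs():
    X, _ = _blobs(0)
    return cluster_topics(X, min_cluster_size=10, seed=0)


def test_identity_merge_preserves_result(clustered_blobs):
    merged = merge(clustered_blobs, {t: t for t in range(1, clustered_blobs.n_topics + 1)})
    assert merged.assignments.equals(clustered_blobs.assignments)
    assert np.allclose(merged.q.to_numpy(), clustered_blobs.q.to_numpy())


def test_merge_all_topics_into_one_conserves_all_mass(clustered_blobs):
    merged = merge(clustered_blobs, {t: 1 for t in range(1, clustered_blobs.n_topics + 1)})
    clustered = clustered_blobs.assignments > 0
    assert np.allclose(merged.q.loc[clustered.to_numpy(), 1], 1.0)


def test_merge_conserves_per_note_mass(clustered_blobs):
    merged = merge(clustered_blobs, {1: "adverse", 2: "adverse", 3: "access"})
    assert np.allclose(
        merged.q.sum(axis=1).to_numpy(), clustered_blobs.q.sum(axis=1).to_numpy(), atol=1e-9
    )
    assert merged.n_topics == 2


def test_merge_requires_total_map(clustered_blobs):
    with pytest.raises(ValueError, match="missing discovered topic"):
        merge(clustered_blobs, {1: "a"})


def test_topic_model_routes_missing_reasons_to_reserved_topic():
    rng = np.random.default_rng(4)
    reasons = [None, ""] + [f"insurance coverage denied {rng.integers(100)}" for _ in range(12)]
    tm = topic_model(reasons, min_cluster_size=5, seed=4)
    assert (tm.assignments.iloc[:2] == 0).all()
    assert tm.q.iloc[0, 0] == 1.0
    assert np.allclose(tm.q.sum(axis=1), 1.0, atol=1e-9)
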