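"""Topic clustering of extracted switching rationales.

Follows the embed -> reduce -> density-cluster -> key-terms recipe: reason
texts are embedded (default: a deterministic TF-IDF representation, with a
plugin seam for transformer embedders), reduced to 5 components by UMAP
with 3 neighbours under Euclidean distance, and clustered by HDBSCAN with
the cluster count chosen by the algorithm. Unclustered notes and notes
with no extracted reason share the reserved topic 0. Per-note topic
weights q(n, k) come from soft cluster membership (inverse squared
distance to cluster centroids in the reduced space) renormalised per note,
and per-topic key terms use class-based TF-IDF: each topic's texts are
pooled into one pseudo-document and term t in topic c is weighted by
freq(t, c) * log(1 + n_topics / n_topics_containing_t).

Discovered topics can be regrouped with a manual merge map, conserving
each note's total topic weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer

__all__ = ["TopicModelResult", "embed", "cluster_topics", "top_terms", "merge", "topic_model"]

NOISE_TOPIC = 0


@dataclass
class TopicModelResult:
    assignments: pd.Series  # per-note topic id; 0 is the noise / no-reason class
    q: pd.DataFrame  # notes x topics soft weights, rows sum to 1
    topic_terms: dict = field(default_factory=dict)  # topic id -> [(term, weight)]
    n_topics: int = 0  # non-noise topic count

    def validate(self) -> None:
        sums = self.q.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("q rows must sum to 1")
        if len(self.assignments) != len(self.q):
            raise ValueError("assignments and q disagree on note count")


def embed(texts, backend="tfidf") -> np.ndarray:
    """Embed reason texts as fixed-dimension vectors.

    ``backend`` is "tfidf" (default), "count", or any callable
    ``f(texts) -> array``; the default backends are deterministic and need
    no model download.
    """
    texts = list(texts)
    if not texts:
        raise ValueError("texts must be a non-empty list")
    if callable(backend):
        return np.asarray(backend(texts), dtype=float)
    if backend == "tfidf":
        vec = TfidfVectorizer()
    elif backend == "count":
        vec = CountVectorizer()
    else:
        raise ValueError(f"unknown embedding backend: {backend!r}")
    return vec.fit_transform(texts).toarray().astype(float)


def _reduce(vectors: np.ndarray, n_components: int, n_neighbors: int, seed: int) -> np.ndarray:
    n_unique = len(np.unique(vectors, axis=0))
    if n_unique <= n_neighbors + 1 or vectors.shape[1] <= n_components:
        # too little structure for a manifold fit; cluster the raw vectors
        return vectors
    import umap  # deferred: heavy numba compilation on first import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=n_components,
            n_neighbors=n_neighbors,
            metric="euclidean",
            random_state=seed,
        )
        return reducer.fit_transform(vectors)


def cluster_topics(
    vectors: np.ndarray,
    *,
    min_cluster_size: int = 10,
    n_components: int = 5,
    n_neighbors: int = 3,
    seed: int = 0,
    index=None,
) -> TopicModelResult:
    """Reduce and density-cluster embedding vectors into topics.

    Cluster count is chosen dynamically by HDBSCAN; unclustered points get
    the reserved noise topic 0. Topic ids 1..K are ordered by descending
    cluster size.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2:
        raise ValueError("vectors must be a 2-D array")
    if len(vectors) < max(10, n_components + 1):
        raise ValueError(f"need at least {max(10, n_components + 1)} vectors, got {len(vectors)}")
    index = pd.RangeIndex(len(vectors)) if index is None else pd.Index(index)

    if len(np.unique(vectors, axis=0)) == 1:
        labels = np.full(len(vectors), 1)
    else:
        reduced = _reduce(vectors, n_components, n_neighbors, seed)
        raw = HDBSCAN(min_cluster_size=min_cluster_size).fit_predict(reduced)
        # order clusters by size; relabel to 1..K, noise (-1) to 0
        ids, counts = np.unique(raw[raw >= 0], return_counts=True)
        order = ids[np.argsort(-counts, kind="stable")]
        remap = {int(c): i + 1 for i, c in enumerate(order)}
        remap[-1] = NOISE_TOPIC
        labels = np.array([remap[int(c)] for c in raw])
        vectors = reduced  # soft membership lives in the reduced space

    n_topics = int(labels.max())
    topics = list(range(n_topics + 1))
    q = np.zeros((len(vectors), n_topics + 1))
    if n_topics == 0:
        q[:, NOISE_TOPIC] = 1.0
    else:
        centroids = np.vstack([vectors[labels == t].mean(axis=0) for t in range(1, n_topics + 1)])
        clustered = labels > 0
        if clustered.any():
            d2 = ((vectors[clustered, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            w = 1.0 / (1.0 + d2)
            q[clustered, 1:] = w / w.sum(axis=1, keepdims=True)
        q[~clustered, NOISE_TOPIC] = 1.0
    result = TopicModelResult(
        assignments=pd.Series(labels, index=index, name="topic"),
        q=pd.DataFrame(q, index=index, columns=topics),
        n_topics=n_topics,
    )
    result.validate()
    return result


def top_terms(texts, assignments, k: int = 10) -> dict:
    """Class-based TF-IDF key terms per topic.

    Each topic's texts are pooled into one pseudo-document; term t in topic
    c scores freq(t, c) * log(1 + n_topics / n_topics_containing_t).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    assignments = pd.Series(list(assignments))
    texts = pd.Series(list(texts))
    if len(texts) != len(assignments):
        raise ValueError("assignments must cover texts")
    topics = sorted(assignments.unique())
    pseudo = [" ".join(texts[assignments == t]) for t in topics]
    vec = CountVectorizer()
    counts = vec.fit_transform(pseudo).toarray()  # topics x terms
    terms = vec.get_feature_names_out()
    n_topics = len(topics)
    df_t = (counts > 0).sum(axis=0)  # topics containing each term
    with np.errstate(divide="ignore"):
        idf = np.log1p(n_topics / np.maximum(df_t, 1))
    weights = counts * idf[None, :]
    out = {}
    for row, t in enumerate(topics):
        order = np.argsort(-weights[row], kind="stable")
        out[t] = [
            (terms[i], float(weights[row, i])) for i in order[:k] if weights[row, i] > 0
        ]
    return out


def merge(result: TopicModelResult, merge_map: dict, texts=None) -> TopicModelResult:
    """Regroup discovered topics under a manual merge map.

    ``merge_map`` must cover every non-noise topic (the noise topic 0 maps
    to itself unless remapped explicitly). q columns are summed within
    merged groups, so each note's total weight is conserved exactly; terms
    are recomputed on the merged classes when ``texts`` is given.
    """
    discovered = [t for t in result.q.columns if t != NOISE_TOPIC]
    missing = [t for t in discovered if t not in merge_map]
    if missing:
        raise ValueError(f"merge map missing discovered topic(s): {missing}")
    full_map = dict(merge_map)
    full_map.setdefault(NOISE_TOPIC, NOISE_TOPIC)
    merged_labels = sorted(set(full_map.values()), key=str)
    q_new = pd.DataFrame(0.0, index=result.q.index, columns=merged_labels)
    for raw, lab in full_map.items():
        if raw in result.q.columns:
            q_new[lab] = q_new[lab] + result.q[raw]
    assignments = result.assignments.map(full_map)
    terms = {}
    if texts is not None:
        terms = top_terms(texts, assignments, k=10)
    else:
        for raw, lab in full_map.items():
            pooled = terms.setdefault(lab, {})
            for term, w in result.topic_terms.get(raw, []):
                pooled[term] = pooled.get(term, 0.0) + w
        terms = {
            lab: sorted(pool.items(), key=lambda kv: (-kv[1], kv[0]))[:10]
            for lab, pool in terms.items()
        }
    out = TopicModelResult(
        assignments=assignments,
        q=q_new,
        topic_terms=terms,
        n_topics=len([l for l in merged_labels if l != NOISE_TOPIC]),
    )
    out.validate()
    return out


def topic_model(
    reasons,
    *,
    backend="tfidf",
    min_cluster_size: int = 10,
    seed: int = 0,
    index=None,
) -> TopicModelResult:
    """Full reason-topic model over a list of reasons (None = no reason).

    Notes without an extracted reason are assigned the reserved topic 0 up
    front and excluded from clustering; the remaining reasons are embedded
    and clustered, and key terms computed per topic.
    """
    reasons = list(reasons)
    index = pd.RangeIndex(len(reasons)) if index is None else pd.Index(index)
    has_reason = np.array([bool(r) and str(r).strip() != "" for r in reasons])
    texts = [str(reasons[i]) for i in np.flatnonzero(has_reason)]
    if len(texts) < 10:
        raise ValueError("need at least 10 non-empty reasons to model topics")
    sub = cluster_topics(
        embed(texts, backend=backend),
        min_cluster_size=min_cluster_size,
        seed=seed,
        index=index[has_reason],
    )
    topics = list(sub.q.columns)
    q = pd.DataFrame(0.0, index=index, columns=topics)
    q.loc[index[~has_reason], NOISE_TOPIC] = 1.0
    q.loc[index[has_reason], :] = sub.q
    assignments = pd.Series(NOISE_TOPIC, index=index, name="topic")
    assignments.loc[index[has_reason]] = sub.assignments
    clustered_texts = pd.Series(texts, index=index[has_reason])
    terms = top_terms(clustered_texts, sub.assignments, k=10)
    result = TopicModelResult(
        assignments=assignments, q=q, topic_terms=terms, n_topics=sub.n_topics
    )
    result.validate()
    return result
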