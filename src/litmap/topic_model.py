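"""Cluster-based topic modelling: reduce, cluster, centroid, rank.

The pipeline follows the Top2Vec family of topic models: document
embeddings are reduced to a low-dimensional manifold (UMAP by default),
dense regions of the reduced space are found by hierarchical
density-based clustering (HDBSCAN), and each cluster is a topic. The
number of topics emerges from the density structure — it is never
supplied by a caller. Documents the clusterer leaves in low-density
regions carry the ``NOISE`` label and stay unassigned unless
nearest-centroid reassignment is requested.

Two conventions matter throughout:

* Centroids and every similarity computation live in the ORIGINAL
  embedding space; the reduced space is used only to find clusters.
* Members of a topic are ranked by cosine similarity of their document
  vector to the topic centroid, which is how the "top ten most
  relevant publications" of a topic are chosen.

Topic words come two ways: nearest vocabulary vectors to the centroid
in the joint embedding space, and class-based TF-IDF over per-topic
pseudo-documents (each topic's texts concatenated; term frequency
damped by corpus-wide frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np

from .embedding import cosine_similarity, tokenize
from .records import PublicationRecord

NOISE = -1


class Reducer(Protocol):
    def reduce(self, vectors: np.ndarray, seed: int) -> np.ndarray: ...


class Clusterer(Protocol):
    def cluster(self, vectors: np.ndarray, seed: int) -> np.ndarray: ...


class PCAReducer:
    """Deterministic linear fallback reducer (sign-fixed principal axes)."""

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def reduce(self, vectors: np.ndarray, seed: int) -> np.ndarray:
        from sklearn.decomposition import PCA

        n_comp = min(self.n_components, *vectors.shape)
        pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
        reduced = pca.fit_transform(vectors)
        # fix component signs so the output is unique, not solver-dependent
        signs = np.sign(np.sum(pca.components_, axis=1))
        signs[signs == 0] = 1.0
        return reduced * signs


class UMAPReducer:
    """Default manifold reducer: 5-d output, cosine metric."""

    def __init__(self, n_components: int = 5, n_neighbors: int = 15, metric: str = "cosine"):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.metric = metric

    def reduce(self, vectors: np.ndarray, seed: int) -> np.ndarray:
        import umap

        reducer = umap.UMAP(
            n_components=min(self.n_components, vectors.shape[1]),
            n_neighbors=min(self.n_neighbors, max(2, vectors.shape[0] - 1)),
            metric=self.metric,
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(vectors), dtype=float)


class HDBSCANClusterer:
    """Density-based hierarchical clusterer; -1 labels are noise."""

    def __init__(self, min_cluster_size: int = 15, min_samples: Optional[int] = None):
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples

    def cluster(self, vectors: np.ndarray, seed: int) -> np.ndarray:
        from sklearn.cluster import HDBSCAN

        model = HDBSCAN(
            min_cluster_size=min(self.min_cluster_size, vectors.shape[0]),
            min_samples=self.min_samples,
            copy=True,
        )
        return model.fit_predict(vectors)


@dataclass
class TopicModelResult:
    """Fitted topic structure over one corpus."""

    assignments: np.ndarray  # per-document topic id, NOISE for outliers
    centroids: dict[int, np.ndarray]  # topic id -> mean member vector (original space)
    topic_sizes: dict[int, int]
    reduced: np.ndarray
    pub_ids: list[str] = field(default_factory=list)

    @property
    def topic_ids(self) -> list[int]:
        return sorted(self.centroids)

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.assignments == NOISE))

    @property
    def has_topics(self) -> bool:
        return bool(self.centroids)

    def members(self, topic_id: int) -> np.ndarray:
        """Row indices of the topic's member documents."""
        if topic_id not in self.centroids:
            raise KeyError(f"unknown topic id {topic_id}")
        return np.flatnonzero(self.assignments == topic_id)


@dataclass
class RankedTopicList:
    """Topic members ordered by similarity to the topic centroid."""

    topic_id: int
    entries: list[tuple[str, float]]  # (pub_id, cosine to centroid), descending


def fit_topic_model(
    doc_vectors: np.ndarray,
    *,
    pub_ids: Optional[Sequence[str]] = None,
    reducer: Optional[Reducer] = None,
    clusterer: Optional[Clusterer] = None,
    seed: int = 0,
    reassign_noise: bool = False,
) -> TopicModelResult:
    """Reduce, cluster and summarise a corpus into topics.

    When every document lands in noise the result simply has no topics
    (``has_topics`` is False) — an empty literature structure is an
    outcome, not an exception. A corpus whose reduced vectors are all
    identical collapses to a single topic holding every document, since
    density clustering has no gradient to separate them.
    """
    doc_vectors = np.asarray(doc_vectors, dtype=float)
    if doc_vectors.ndim != 2 or doc_vectors.shape[0] == 0:
        raise ValueError("doc_vectors must be a non-empty 2-d matrix")
    n_docs = doc_vectors.shape[0]
    ids = list(pub_ids) if pub_ids is not None else [str(i) for i in range(n_docs)]
    if len(ids) != n_docs:
        raise ValueError("pub_ids length must match the number of documents")

    reducer = reducer if reducer is not None else UMAPReducer()
    clusterer = clusterer if clusterer is not None else HDBSCANClusterer()

    reduced = reducer.reduce(doc_vectors, seed)

    if np.allclose(reduced, reduced[0]):
        labels = np.zeros(n_docs, dtype=int)
    else:
        labels = np.asarray(clusterer.cluster(reduced, seed), dtype=int)

    centroids: dict[int, np.ndarray] = {}
    sizes: dict[int, int] = {}
    for topic_id in sorted(set(labels[labels != NOISE])):
        mask = labels == topic_id
        centroids[int(topic_id)] = doc_vectors[mask].mean(axis=0)
        sizes[int(topic_id)] = int(mask.sum())

    if reassign_noise and centroids:
        for i in np.flatnonzero(labels == NOISE):
            best = max(
                centroids,
                key=lambda t: (cosine_similarity(doc_vectors[i], centroids[t]), -t),
            )
            labels[i] = best
        for topic_id in centroids:
            mask = labels == topic_id
            centroids[topic_id] = doc_vectors[mask].mean(axis=0)
            sizes[topic_id] = int(mask.sum())

    return TopicModelResult(
        assignments=labels,
        centroids=centroids,
        topic_sizes=sizes,
        reduced=reduced,
        pub_ids=ids,
    )


def rank_topic_documents(
    result: TopicModelResult,
    doc_vectors: np.ndarray,
    topic_id: int,
    n: int = 10,
) -> RankedTopicList:
    """Top-``n`` members of a topic by cosine to its centroid.

    The default of ten reflects how many suggestions a reader can
    usefully triage per topic. Ties are broken by pub_id ascending.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    centroid = result.centroids.get(topic_id)
    if centroid is None:
        raise KeyError(f"unknown topic id {topic_id}")
    doc_vectors = np.asarray(doc_vectors, dtype=float)
    scored = [
        (result.pub_ids[i], cosine_similarity(doc_vectors[i], centroid))
        for i in result.members(topic_id)
    ]
    scored.sort(key=lambda e: (-e[1], e[0]))
    return RankedTopicList(topic_id=topic_id, entries=scored[:n])


def topic_words_nearest(
    centroid: np.ndarray,
    word_vectors: np.ndarray,
    vocabulary: Sequence[str],
    k: int,
) -> list[tuple[str, float]]:
    """``k`` vocabulary terms nearest the centroid in the joint space."""
    if len(vocabulary) != word_vectors.shape[0]:
        raise ValueError("vocabulary and word_vectors are misaligned")
    if k < 0:
        raise ValueError("k must be non-negative")
    scored = [
        (term, cosine_similarity(word_vectors[i], centroid))
        for i, term in enumerate(vocabulary)
    ]
    scored.sort(key=lambda e: (-e[1], e[0]))
    return scored[:k]


def topic_words_ctfidf(
    records_by_topic: dict[int, Sequence[PublicationRecord]],
    k: int,
) -> dict[int, list[tuple[str, float]]]:
    """Class-based TF-IDF topic words.

    Each topic's documents are concatenated into one pseudo-document;
    a term scores ``tf(t, c) * log(1 + A / f(t))`` where ``tf`` is the
    term's count in the topic's pseudo-document, ``A`` the mean
    pseudo-document token count and ``f(t)`` the term's total corpus
    frequency. Ubiquitous terms are demoted by the damping factor, so
    no stopword list is needed.
    """
    if not records_by_topic:
        raise ValueError("at least one topic is required")
    tf: dict[int, dict[str, int]] = {}
    corpus_freq: dict[str, int] = {}
    lengths: list[int] = []
    for topic_id, recs in records_by_topic.items():
        counts: dict[str, int] = {}
        for rec in recs:
            for token in tokenize(rec.text):
                counts[token] = counts.get(token, 0) + 1
                corpus_freq[token] = corpus_freq.get(token, 0) + 1
        tf[topic_id] = counts
        lengths.append(sum(counts.values()))

    mean_len = float(np.mean(lengths))
    out: dict[int, list[tuple[str, float]]] = {}
    for topic_id, counts in tf.items():
        scored = [
            (term, count * float(np.log1p(mean_len / corpus_freq[term])))
            for term, count in counts.items()
        ]
        scored.sort(key=lambda e: (-e[1], e[0]))
        out[topic_id] = scored[:k]
    return out


def save_model(result: TopicModelResult, directory: str | Path) -> None:
    """Persist centroids, assignments and reduced vectors to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = result.topic_ids
    if ids:
        np.save(directory / "centroids.npy", np.vstack([result.centroids[t] for t in ids]))
    (directory / "topics.tsv").write_text(
        "\n".join(str(t) for t in ids) + ("\n" if ids else ""), encoding="utf-8"
    )
    with (directory / "assignments.tsv").open("w", encoding="utf-8") as fh:
        fh.write("pub_id\ttopic_id\n")
        for pub_id, label in zip(result.pub_ids, result.assignments):
            fh.write(f"{pub_id}\t{int(label)}\n")
    np.save(directory / "reduced.npy", result.reduced)


def load_model(directory: str | Path) -> TopicModelResult:
    directory = Path(directory)
    topic_ids = [
        int(t) for t in (directory / "topics.tsv").read_text().split() if t.strip()
    ]
    centroid_matrix = (
        np.load(directory / "centroids.npy") if topic_ids else np.empty((0, 0))
    )
    lines = (directory / "assignments.tsv").read_text(encoding="utf-8").splitlines()[1:]
    pub_ids, labels = [], []
    for line in lines:
        pub_id, label = line.split("\t")
        pub_ids.append(pub_id)
        labels.append(int(label))
    assignments = np.asarray(labels, dtype=int)
    return TopicModelResult(
        assignments=assignments,
        centroids={t: centroid_matrix[i] for i, t in enumerate(topic_ids)},
        topic_sizes={t: int(np.sum(assignments == t)) for t in topic_ids},
        reduced=np.load(directory / "reduced.npy"),
        pub_ids=pub_ids,
    )
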