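"""Label-driven semantic relation graphs.

After a reader marks publications relevant and names the theme each one
belongs to, those named themes become *user topics*: each topic vector
is the mean of its members' document embeddings, L2-normalised so that
all comparisons live on the cosine sphere. The relation graph places
user topics alongside the original search phrases (group-1 and group-2
alias terms, embedded with the same embedder as the documents) and
connects every user topic to its ``k`` most similar other nodes by
undirected cosine-weighted edges. Term nodes receive edges but do not
initiate them by default — the graph answers "what is each discovered
theme close to?", not the converse — though ``terms_initiate=True``
flips that.

Node roles map to display colours: user topics red, group-1 terms
green, group-2 terms blue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from pydantic import BaseModel, Field

from .embedding import Embedder, cosine_similarity
from .query import SearchSpec

ROLE_COLOURS = {"user_topic": "red", "group1_term": "green", "group2_term": "blue"}


class LabelAssignment(BaseModel):
    """One reader judgement: is this publication relevant, and to what theme."""

    pub_id: str = Field(min_length=1)
    relevant: bool
    user_label: str = ""

    def model_post_init(self, __context) -> None:
        if self.relevant and not self.user_label.strip():
            raise ValueError(
                f"relevant publication {self.pub_id!r} needs a non-empty user_label"
            )


@dataclass
class GraphNode:
    node_id: str
    display_name: str
    role: str  # user_topic | group1_term | group2_term
    vector: np.ndarray


def aggregate_label_topics(
    assignments: Sequence[LabelAssignment],
    doc_vectors: Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Mean-then-normalise document vectors per user label.

    Non-relevant assignments are ignored; a relevant publication with no
    document vector is an error naming the id. Order of assignments
    never matters (the mean is order-free).
    """
    _check_unique(assignments)
    members: dict[str, list[np.ndarray]] = {}
    for a in assignments:
        if not a.relevant:
            continue
        if a.pub_id not in doc_vectors:
            raise KeyError(f"no document vector for relevant publication {a.pub_id!r}")
        members.setdefault(a.user_label, []).append(np.asarray(doc_vectors[a.pub_id], float))
    if not members:
        raise ValueError("no relevant assignments: nothing to aggregate")
    out: dict[str, np.ndarray] = {}
    for label, vectors in members.items():
        mean = np.mean(vectors, axis=0)
        norm = np.linalg.norm(mean)
        if norm == 0:
            raise ValueError(f"topic {label!r} has a zero mean vector")
        out[label] = mean / norm
    return out


def _check_unique(assignments: Sequence[LabelAssignment]) -> None:
    seen: set[str] = set()
    for a in assignments:
        if a.pub_id in seen:
            raise ValueError(f"duplicate assignment for publication {a.pub_id!r}")
        seen.add(a.pub_id)


def build_relation_graph(
    topic_vectors: Mapping[str, np.ndarray],
    search_spec: Optional[SearchSpec],
    embedder: Optional[Embedder],
    k: int = 3,
    terms_initiate: bool = False,
) -> nx.Graph:
    """Connect each topic to its ``k`` most similar other nodes.

    Nodes are the user topics plus one node per search phrase of each
    alias group (embedded via ``embedder.embed_phrase``). Similarities
    are computed between all node pairs; each initiating node
    contributes undirected edges to its top-``k`` neighbours, ties at
    the cut broken by node id ascending, and duplicate edges are merged
    (weights are symmetric so merging never changes a weight).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nodes: list[GraphNode] = [
        GraphNode(f"topic:{label}", label, "user_topic", np.asarray(vec, float))
        for label, vec in topic_vectors.items()
    ]
    if search_spec is not None:
        if embedder is None:
            raise ValueError("an embedder is required to embed search phrases")
        for role, group in zip(
            ("group1_term", "group2_term"), (search_spec.group1, search_spec.group2)
        ):
            if group is None:
                continue
            for phrase in group.phrases:
                nodes.append(
                    GraphNode(f"term:{phrase}", phrase, role, embedder.embed_phrase(phrase))
                )
    if len(nodes) < 2:
        raise ValueError("a relation graph needs at least two nodes")

    graph = nx.Graph()
    for node in nodes:
        graph.add_node(
            node.node_id,
            display_name=node.display_name,
            role=node.role,
            colour=ROLE_COLOURS[node.role],
        )

    for source in nodes:
        if source.role != "user_topic" and not terms_initiate:
            continue
        scored = [
            (other, cosine_similarity(source.vector, other.vector))
            for other in nodes
            if other.node_id != source.node_id
        ]
        scored.sort(key=lambda e: (-e[1], e[0].node_id))
        for other, weight in scored[:k]:
            graph.add_edge(source.node_id, other.node_id, weight=weight)
    return graph


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def to_node_link(graph: nx.Graph) -> dict:
    """JSON-serialisable node-link representation."""
    return nx.node_link_data(graph, edges="links")
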