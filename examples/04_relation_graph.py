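"""Aggregate reader labels into topic vectors and build the relation graph.

Each user-named theme becomes a node (mean of its members' embeddings,
normalised); the search phrases join as green/blue term nodes; every
theme connects to its three most similar other nodes with cosine
weights.
"""

from litmap import (
    CorpusSpec,
    HashingEmbedder,
    LabelAssignment,
    SearchSpec,
    aggregate_label_topics,
    build_relation_graph,
    embed_corpus,
    generate_corpus,
    parse_pubmed_xml,
)

spec = CorpusSpec(n_topics=2, docs_per_topic=20, topic_vocab_overlap=0.1, seed=3)
xml, manifest = generate_corpus(spec)
records = parse_pubmed_xml(xml)
embedder = HashingEmbedder(dim=128, seed=1)
vectors, pub_ids = embed_corpus(records, embedder)
doc_vecs = dict(zip(pub_ids, vectors))

# a reader marks six publications relevant under two themes
labels = [
    LabelAssignment(pub_id=pid, relevant=True, user_label=f"theme {manifest.topics[pid]}")
    for pid in pub_ids[:3] + pub_ids[-3:]
]
topic_vectors = aggregate_label_topics(labels, doc_vecs)

search = SearchSpec.from_groups([["t0w000", "t0w001"], ["t1w000"]])
graph = build_relation_graph(topic_vectors, search, embedder, k=3)

print(f"graph: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")
for node, data in graph.nodes(data=True):
    print(f"  {node:20s} role={data['role']:12s} colour={data['colour']}")
for u, v, w in graph.edges(data="weight"):
    print(f"  {u} -- {v}: cosine {w:.3f}")
# High-weight edges join themes (red) to the search terms (green/blue)
# whose vocabulary they share.
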