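# Methods

## Pipeline model

`litmap` treats assisted literature review as four coupled stages:
query construction, retrieval, unsupervised topic consolidation, and
reader-in-the-loop evaluation. The topic stage follows the
cluster-based (Top2Vec/BERTopic-family) view of topic modelling: a
topic is a dense region of document-embedding space, not a latent
multinomial. Its assumptions, made explicit:

* documents about one theme are mutually closer in embedding space
  than documents about different themes (depends entirely on the
  embedder);
* low-dimensional manifold reduction preserves enough of that
  neighbourhood structure for density clustering;
* the centroid (arithmetic mean of member vectors) is a usable proxy
  for a topic's semantic centre, so cosine-to-centroid orders members
  by representativeness.

Reduction is used **only** to find clusters. Centroids, member
ranking, topic-word extraction and the relation graph all operate in
the original embedding space, where cosine similarity is meaningful
across documents, words and phrases.

## Components and parameters

**Query construction.** Up to two alias groups; OR within, AND
between; phrases unquoted and untagged, as a user would type them. A
third group is a validation error, not a silent truncation. Keyword
specificity is the mean phrase length in Unicode code points, internal
spaces included, pooled over all phrases in one averaging step.

**Parsing.** `PubDate/Year` is preferred for the year, then the first
four-digit year in `MedlineDate`, then `ArticleDate/Year`; MeSH
qualifiers are ignored (descriptor names only); abstract sections are
joined with newlines. Articles with neither title nor abstract carry
no usable text and are dropped with a warning; an article with an
abstract but no title keeps the abstract's first 80 characters as its
title so the record's title invariant holds.

**Embedding.** The `Embedder` contract (documents, vocabulary terms
and phrases into one d-dimensional space) is pluggable; production use
expects a pretrained sentence encoder. The shipped `HashingEmbedder`
(default d=256) hashes tokens into buckets via seeded blake2b with a
pseudo-random sign, TF-weights and L2-normalises. It is bit-reproducible
and needs no model artefacts, but its notion of similarity is lexical
overlap only: synonymy, negation and word order are invisible to it.
Search phrases are embedded through `embed_phrase` on the whole phrase,
the same path documents take.

**Topic model.** Defaults mirror the canonical parameters of the
cited algorithms: UMAP to 5 components with cosine metric; HDBSCAN
with minimum cluster size 15 (scaled down to 5 in tests and examples,
matching corpora of tens rather than hundreds of documents). Both are
injected behaviours; tests use a deterministic PCA reducer with
sign-fixed components so fits are bit-reproducible. Noise documents
stay unassigned by default; `reassign_noise=True` moves each to its
nearest centroid and recomputes centroids once. Density clustering
returns all-noise on exactly coincident points, so a zero-spread
reduced matrix is special-cased to a single topic — the honest answer
for a corpus of identical documents. Ranking ties break by pub_id
ascending; topic-word ties break lexicographically.

**Class-based TF-IDF.** The literature describes the pseudo-document
weighting in prose; the formula implemented is the BERTopic-style
reading: `tf(t, c) · log(1 + A / f(t))` with `A` the mean
pseudo-document token count and `f(t)` the corpus-wide term frequency.
Tokenisation is lowercase, split on non-alphanumerics, tokens shorter
than two characters dropped, no stopword list — the inverse-class
factor demotes ubiquitous terms instead.

**Relation graph.** Topic vectors are mean-then-L2-normalised so all
similarities live on the cosine sphere. Eligible edge targets for a
topic include both other topics and term nodes; term nodes receive but
do not initiate edges (the graph describes each discovered theme's
neighbourhood). `terms_initiate=True` flips that. k defaults to 3;
ties at the k-th similarity break by node id.

**Evaluation.** User-agreed relevance counts only topics with at least
one relevant label — an untouched topic is evidence of nothing — and
reports `100 · relevant / suggested` over those topics' suggestions;
reported values round to one decimal, internal values do not. Rank
positions are 1-based. Correlations use Spearman's rank coefficient
(no linearity assumption, robust to the heavy ties relevance
percentages produce); a constant series is reported as undefined
rather than coerced to zero.

**C_v coherence.** Boolean sliding windows (default 110 tokens, the
measure's canonical width) over each document's token stream define
word and pair probabilities; a document shorter than the window
contributes one window. Each of a topic's top-N words (default 10)
gets an NPMI vector against all N words (epsilon 1e-12 smoothing);
word score = cosine of its vector with the summed topic vector; topic
score = mean over words. Words absent from the corpus receive epsilon
probability; a topic whose words are all absent is undefined and
excluded from the corpus mean. Two words co-occurring in every window
make all NPMI vectors parallel, so the score's upper limit of exactly
1 is reached regardless of the epsilon.

## Synthetic corpus generator

The generator emulates what the pipeline consumes — efetch-dialect XML
with planted structure — not biomedical language. Each topic owns a
vocabulary of `vocab_size` synthetic tokens with Zipf-shaped
frequencies (exponent 1.1, echoing natural-language skew); with
probability `topic_vocab_overlap` a token is drawn from a shared pool
instead, making separability a single dial. Document lengths are
uniform on 80–200 tokens, roughly the span of structured abstracts
with titles. MeSH/chemical/keyword pools and a year range are sampled
per topic and recorded, with everything else, in a ground-truth
manifest. Reference rankings plant a relevant topic's members in a
contiguous block at a configurable start rank (default: the tail), so
rank statistics have closed-form expected values.

What passing tests therefore show: the pipeline's mechanics —
parsing, clustering, ranking, counting, graph construction, coherence
— are correct against exact oracles. What they do not show: that any
particular embedder separates real biomedical abstracts, or that
relevance percentages observed on synthetic corpora transfer to human
labelling behaviour. The 18-search reference relevance table bundled
in `litmap.studydata` is observational input, not something the
package can regenerate.

## Numerical choices and degenerate inputs

Cosine similarity raises on zero vectors (undefined, not zero) and
clips to [-1, 1] against floating-point drift. Means over empty sets
(no relevant topics, empty relevant set, all-absent coherence topics)
are reported as undefined/None, never as 0. PCA components are
sign-fixed (sum of loadings positive) so reduced coordinates do not
depend on LAPACK sign conventions. All randomness flows through
`numpy.random.default_rng` seeds carried in the corpus/model
parameters; fixed seeds give byte-identical XML and bit-identical
fits.

Test and acceptance problem sizes — 2–3 topics of 15–30 documents,
hash dimension 64–128, 20 corpora for the recovery sweep — are the
smallest scales at which planted structure is reliably recoverable,
keeping the full suite in the tens of seconds.

## Known limitations

* The hashing embedder cannot model synonymy; real deployments should
  inject a sentence encoder, and no claim is made that any particular
  encoder reproduces previously published embeddings.
* Label-driven *refitting* of the topic model is out of scope: labels
  drive graph regeneration only, as no refinement algorithm is
  specified for the hybrid loop.
* Full-text retrieval is not attempted; body text is whatever the
  fetched XML carries (normally the abstract).
* MeSH frequencies count descriptor names; grouping by tree branch is
  a possible alternative reading of "MeSH categories" that was not
  adopted.
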