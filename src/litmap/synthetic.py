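"""Synthetic PubMed-like corpora with planted topic structure.

Offline testing of the whole pipeline needs corpora whose ground truth
is known exactly. The generator plants ``n_topics`` topics, each with
its own Zipf-shaped unigram vocabulary; a configurable fraction of each
document's tokens is instead drawn from a vocabulary shared across all
topics, so topic separability is a dial (overlap 0 means fully disjoint
content vocabularies). Each record carries topic-specific MeSH
descriptors, chemical names, author keywords and a publication year,
and is serialised as efetch-dialect XML so the real parser is exercised
end to end. The accompanying manifest records every generated field
per publication — it is the oracle tests compare against.

The defaults — Zipf exponent 1.1 within a topic, document lengths of
80–200 tokens — emulate the skewed word-frequency and abstract-length
profile of real biomedical abstracts at a scale where clustering is
recoverable; they make no claim of linguistic realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional
from xml.sax.saxutils import escape

import numpy as np
from pydantic import BaseModel, Field, model_validator


class CorpusSpec(BaseModel):
    """Parameters of one planted-topic corpus."""

    n_topics: int = Field(default=3, ge=1)
    docs_per_topic: int = Field(default=30, ge=1)
    vocab_size: int = Field(default=200, ge=2, description="content words per topic")
    topic_vocab_overlap: float = Field(default=0.2, ge=0.0, lt=1.0)
    zipf_exponent: float = Field(default=1.1, gt=0)
    doc_length_range: tuple[int, int] = (80, 200)
    title_tokens: int = Field(default=8, ge=1)
    mesh_per_topic: int = Field(default=4, ge=1)
    chemicals_per_topic: int = Field(default=3, ge=1)
    keywords_per_topic: int = Field(default=4, ge=1)
    year_range: tuple[int, int] = (2000, 2024)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CorpusSpec":
        lo, hi = self.doc_length_range
        if not (1 <= lo <= hi):
            raise ValueError("doc_length_range must satisfy 1 <= lo <= hi")
        y0, y1 = self.year_range
        if y0 > y1:
            raise ValueError("year_range must be (lo, hi) with lo <= hi")
        shared = int(round(self.topic_vocab_overlap * self.vocab_size))
        if self.topic_vocab_overlap > 0 and shared < 1:
            raise ValueError(
                "vocab_size too small for the requested overlap fraction"
            )
        return self


@dataclass
class GroundTruthManifest:
    """Everything the generator decided, per publication."""

    spec: CorpusSpec
    topics: dict[str, int]  # pub_id -> planted topic id
    fields: dict[str, dict]  # pub_id -> generated record fields

    def pub_ids(self) -> list[str]:
        return list(self.topics)

    def members(self, topic_id: int) -> list[str]:
        return [pid for pid, t in self.topics.items() if t == topic_id]

    def to_json(self) -> str:
        return json.dumps(
            {
                "spec": self.spec.model_dump(),
                "topics": self.topics,
                "fields": self.fields,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        raw = json.loads(text)
        return cls(
            spec=CorpusSpec.model_validate(raw["spec"]),
            topics=raw["topics"],
            fields=raw["fields"],
        )


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    weights = 1.0 / np.arange(1, n + 1) ** exponent
    return weights / weights.sum()


def _topic_pools(spec: CorpusSpec) -> tuple[list[list[str]], list[str]]:
    """Exclusive vocabularies per topic plus the shared pool."""
    exclusive = [
        [f"t{t}w{j:03d}" for j in range(spec.vocab_size)] for t in range(spec.n_topics)
    ]
    n_shared = int(round(spec.topic_vocab_overlap * spec.vocab_size))
    shared = [f"shw{j:03d}" for j in range(n_shared)]
    return exclusive, shared


def generate_corpus(spec: CorpusSpec) -> tuple[bytes, GroundTruthManifest]:
    """Generate the efetch-dialect XML and its ground-truth manifest.

    A fixed seed yields byte-identical XML. Every record round-trips
    through the PubMed parser with no loss.
    """
    rng = np.random.default_rng(spec.seed)
    exclusive, shared = _topic_pools(spec)
    zipf_excl = _zipf_probs(spec.vocab_size, spec.zipf_exponent)
    zipf_shared = _zipf_probs(len(shared), spec.zipf_exponent) if shared else None

    mesh_pools = [
        [f"Descriptor T{t} {chr(65 + i)}" for i in range(spec.mesh_per_topic)]
        for t in range(spec.n_topics)
    ]
    chem_pools = [
        [f"Compound T{t} {chr(65 + i)}" for i in range(spec.chemicals_per_topic)]
        for t in range(spec.n_topics)
    ]
    kw_pools = [
        [f"keyword t{t} {chr(97 + i)}" for i in range(spec.keywords_per_topic)]
        for t in range(spec.n_topics)
    ]

    topics: dict[str, int] = {}
    fields: dict[str, dict] = {}
    articles: list[str] = []
    pub_counter = 10000000

    for topic in range(spec.n_topics):
        for _ in range(spec.docs_per_topic):
            pub_counter += 1
            pub_id = str(pub_counter)
            length = int(rng.integers(spec.doc_length_range[0], spec.doc_length_range[1] + 1))
            tokens: list[str] = []
            for _ in range(length):
                if shared and rng.random() < spec.topic_vocab_overlap:
                    tokens.append(str(rng.choice(shared, p=zipf_shared)))
                else:
                    tokens.append(str(rng.choice(exclusive[topic], p=zipf_excl)))
            title = " ".join(tokens[: spec.title_tokens])
            abstract = " ".join(tokens[spec.title_tokens :])

            n_mesh = int(rng.integers(1, spec.mesh_per_topic + 1))
            mesh = [mesh_pools[topic][i] for i in sorted(
                rng.choice(spec.mesh_per_topic, size=n_mesh, replace=False))]
            n_chem = int(rng.integers(0, spec.chemicals_per_topic + 1))
            chems = [chem_pools[topic][i] for i in sorted(
                rng.choice(spec.chemicals_per_topic, size=n_chem, replace=False))]
            n_kw = int(rng.integers(1, spec.keywords_per_topic + 1))
            kws = [kw_pools[topic][i] for i in sorted(
                rng.choice(spec.keywords_per_topic, size=n_kw, replace=False))]
            year = int(rng.integers(spec.year_range[0], spec.year_range[1] + 1))

            topics[pub_id] = topic
            fields[pub_id] = {
                "pub_id": pub_id,
                "title": title,
                "body_text": abstract,
                "year": year,
                "mesh_terms": mesh,
                "chemicals": chems,
                "keywords": kws,
            }
            articles.append(_article_xml(pub_id, title, abstract, year, mesh, chems, kws))

    xml = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        "<PubmedArticleSet>\n" + "".join(articles) + "</PubmedArticleSet>\n"
    ).encode("utf-8")
    return xml, GroundTruthManifest(spec=spec, topics=topics, fields=fields)


def _article_xml(
    pub_id: str,
    title: str,
    abstract: str,
    year: int,
    mesh: list[str],
    chems: list[str],
    kws: list[str],
) -> str:
    mesh_xml = "".join(
        f"        <MeshHeading><DescriptorName>{escape(m)}</DescriptorName></MeshHeading>\n"
        for m in mesh
    )
    chem_xml = "".join(
        f"        <Chemical><NameOfSubstance>{escape(c)}</NameOfSubstance></Chemical>\n"
        for c in chems
    )
    kw_xml = "".join(f"        <Keyword>{escape(k)}</Keyword>\n" for k in kws)
    return (
        "  <PubmedArticle>\n"
        "    <MedlineCitation>\n"
        f"      <PMID>{pub_id}</PMID>\n"
        "      <Article>\n"
        f"        <Journal><JournalIssue><PubDate><Year>{year}</Year></PubDate>"
        "</JournalIssue></Journal>\n"
        f"        <ArticleTitle>{escape(title)}</ArticleTitle>\n"
        f"        <Abstract><AbstractText>{escape(abstract)}</AbstractText></Abstract>\n"
        "      </Article>\n"
        "      <ChemicalList>\n" + chem_xml + "      </ChemicalList>\n"
        "      <MeshHeadingList>\n" + mesh_xml + "      </MeshHeadingList>\n"
        '      <KeywordList Owner="NOTNLM">\n' + kw_xml + "      </KeywordList>\n"
        "    </MedlineCitation>\n"
        "  </PubmedArticle>\n"
    )


def generate_reference_ranking(
    manifest: GroundTruthManifest,
    relevant_topic: int,
    noise: float = 0.0,
    seed: int = 0,
    start_rank: Optional[int] = None,
) -> list[str]:
    """A full-corpus ranking with the relevant topic planted at depth.

    The relevant topic's publications occupy a contiguous block of
    ranks beginning at ``start_rank`` (1-based; default places them at
    the very tail), shuffled within the block, so the planted mean rank
    is ``start_rank + (m - 1) / 2`` exactly. With probability ``noise``
    each relevant publication is instead swapped with a random
    publication elsewhere in the list.
    """
    if not (0.0 <= noise <= 1.0):
        raise ValueError("noise must be within [0, 1]")
    members = manifest.members(relevant_topic)
    if not members:
        raise ValueError(f"topic {relevant_topic} not present in manifest")
    all_ids = manifest.pub_ids()
    others = [pid for pid in all_ids if pid not in set(members)]
    n_total, m = len(all_ids), len(members)
    if start_rank is None:
        start_rank = n_total - m + 1
    if not (1 <= start_rank <= n_total - m + 1):
        raise ValueError("start_rank places the relevant block outside the ranking")

    rng = np.random.default_rng(seed)
    members = list(members)
    others = list(others)
    rng.shuffle(members)
    rng.shuffle(others)

    ranking: list[Optional[str]] = [None] * n_total
    block = range(start_rank - 1, start_rank - 1 + m)
    for pos, pid in zip(block, members):
        ranking[pos] = pid
    free = [i for i in range(n_total) if ranking[i] is None]
    for pos, pid in zip(free, others):
        ranking[pos] = pid

    if noise > 0 and n_total > 1:
        for pos in list(block):
            if rng.random() < noise:
                other = int(rng.integers(0, n_total))
                ranking[pos], ranking[other] = ranking[other], ranking[pos]
    return [pid for pid in ranking if pid is not None]


def write_corpus(
    spec: CorpusSpec, directory: str | Path, stem: str = "corpus"
) -> tuple[Path, Path]:
    """Write XML and manifest side by side; returns their paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    xml, manifest = generate_corpus(spec)
    xml_path = directory / f"{stem}.xml"
    manifest_path = directory / f"{stem}.manifest.json"
    xml_path.write_bytes(xml)
    manifest_path.write_text(manifest.to_json(), encoding="utf-8")
    return xml_path, manifest_path
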