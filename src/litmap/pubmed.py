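"""PubMed retrieval and XML parsing.

``parse_pubmed_xml`` turns an efetch ``PubmedArticleSet`` document into
:class:`~litmap.records.PublicationRecord` objects, in article order —
the article order of a retrieved set is the engine's relevance ranking
and is preserved end to end. ``fetch_publications`` is a thin Entrez
E-utilities adapter (esearch then efetch) with an injectable transport
so the rest of the pipeline is testable without network access.

Field extraction rules:

* ``title`` — ``ArticleTitle``, with inline markup flattened.
* ``body_text`` — all ``AbstractText`` sections joined with newlines.
  Full text is used when the XML carries it, but is never fetched
  separately (efetch supplies abstracts).
* ``year`` — ``PubDate/Year``; else the first four-digit year inside
  ``MedlineDate``; else ``ArticleDate/Year``; else unknown.
* ``mesh_terms`` — ``DescriptorName`` text only (qualifiers ignored).
* ``chemicals`` — ``NameOfSubstance`` text.
* ``keywords`` — ``Keyword`` text.

Articles with neither a title nor an abstract carry no usable text and
are dropped with a warning. An article with an abstract but no title is
kept, its title derived from the opening of the abstract.
"""

from __future__ import annotations

import logging
import re
import time
from typing import Callable, Optional

from lxml import etree

from .records import PublicationRecord

logger = logging.getLogger(__name__)

_YEAR_RE = re.compile(r"\b(1[89]\d{2}|20\d{2}|2100)\b")

# transport: (query, max_results) -> raw efetch XML bytes
Transport = Callable[[str, int], bytes]


class PubMedParseError(ValueError):
    """Malformed XML, reporting the parser's position."""


def _text(node: Optional[etree._Element]) -> str:
    if node is None:
        return ""
    return "".join(node.itertext()).strip()


def _extract_year(citation: etree._Element) -> Optional[int]:
    year = _text(citation.find(".//JournalIssue/PubDate/Year"))
    if year.isdigit():
        return int(year)
    medline_date = _text(citation.find(".//JournalIssue/PubDate/MedlineDate"))
    m = _YEAR_RE.search(medline_date)
    if m:
        return int(m.group(1))
    art_year = _text(citation.find(".//ArticleDate/Year"))
    if art_year.isdigit():
        return int(art_year)
    return None


def parse_pubmed_xml(xml_document: bytes | str) -> list[PublicationRecord]:
    """Parse an efetch ``PubmedArticleSet`` document into records.

    Record order equals article order in the XML. A document with zero
    articles yields an empty list; malformed XML raises
    :class:`PubMedParseError` naming the offending position.
    """
    if isinstance(xml_document, str):
        xml_document = xml_document.encode("utf-8")
    try:
        root = etree.fromstring(xml_document)
    except etree.XMLSyntaxError as exc:
        raise PubMedParseError(f"malformed PubMed XML: {exc}") from exc

    records: list[PublicationRecord] = []
    for article in root.iter("PubmedArticle"):
        citation = article.find("MedlineCitation")
        if citation is None:
            continue
        pub_id = _text(citation.find("PMID"))
        title = _text(citation.find(".//Article/ArticleTitle"))
        abstract_parts = [
            _text(node)
            for node in citation.findall(".//Article/Abstract/AbstractText")
        ]
        body = "\n".join(p for p in abstract_parts if p)

        if not title and not body:
            logger.warning("dropping article %s: no title and no abstract", pub_id or "?")
            continue
        if not title:
            title = body[:80].strip()

        records.append(
            PublicationRecord(
                pub_id=pub_id,
                title=title,
                body_text=body,
                year=_extract_year(citation),
                mesh_terms=[
                    _text(d)
                    for d in citation.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
                    if _text(d)
                ],
                chemicals=[
                    _text(c)
                    for c in citation.findall(".//ChemicalList/Chemical/NameOfSubstance")
                    if _text(c)
                ],
                keywords=[
                    _text(k)
                    for k in citation.findall(".//KeywordList/Keyword")
                    if _text(k)
                ],
            )
        )
    return records


def _entrez_transport(email: str, api_key: Optional[str] = None) -> Transport:
    """Default network transport via Biopython's Entrez client."""

    def fetch(query: str, max_results: int) -> bytes:
        from Bio import Entrez

        Entrez.email = email
        if api_key:
            Entrez.api_key = api_key
        with Entrez.esearch(db="pubmed", term=query, retmax=max_results) as handle:
            result = Entrez.read(handle)
        ids = result.get("IdList", [])
        if not ids:
            return b'<?xml version="1.0" ?>\n<PubmedArticleSet></PubmedArticleSet>'
        with Entrez.efetch(db="pubmed", id=",".join(ids), retmode="xml") as handle:
            return handle.read()

    return fetch


def fetch_publications(
    query: str,
    max_results: int,
    *,
    email: str = "",
    api_key: Optional[str] = None,
    transport: Optional[Transport] = None,
    retries: int = 3,
    backoff: float = 1.0,
) -> bytes:
    """Fetch the article-set XML for up to ``max_results`` best-match results.

    The transport returns the raw XML bytes unchanged, so downstream
    parsing sees exactly what the service emitted and article order (the
    reference ranking) is preserved. Transient failures are retried with
    exponential backoff.
    """
    if not query.strip():
        raise ValueError("query must be non-empty")
    if max_results < 1:
        raise ValueError("max_results must be >= 1")
    if transport is None:
        if not email:
            raise ValueError("a contact email is required for live Entrez requests")
        transport = _entrez_transport(email, api_key)

    last_exc: Optional[Exception] = None
    for attempt in range(retries):
        try:
            return transport(query, max_results)
        except Exception as exc:  # pragma: no cover - network path
            last_exc = exc
            if attempt < retries - 1:
                time.sleep(backoff * 2**attempt)
    raise RuntimeError(f"PubMed fetch failed after {retries} attempts") from last_exc
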