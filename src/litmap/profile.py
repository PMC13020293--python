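"""Per-topic meta-information profiles.

A topic's profile is the set of five summaries a reader sees alongside
its publication list: the topic's characteristic words, and frequency
tables of MeSH descriptors, chemical substances, author keywords and
publication years across the topic's records. Frequency tables count a
term once per record (a descriptor repeated inside one record is not
double-counted) and are ordered by count descending, then name
ascending. Records with an unknown year are omitted from the year
histogram, so its counts sum to at most the topic size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .records import PublicationRecord


@dataclass
class TopicProfile:
    topic_words: list[tuple[str, float]]
    mesh_freq: dict[str, int]
    chemical_freq: dict[str, int]
    keyword_freq: dict[str, int]
    year_hist: dict[int, int] = field(default_factory=dict)


def _freq_table(per_record_terms: Sequence[Sequence[str]]) -> dict[str, int]:
    counter: Counter[str] = Counter()
    for terms in per_record_terms:
        counter.update(set(terms))  # dedup within record
    return dict(sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])))


def build_topic_profile(
    records_in_topic: Sequence[PublicationRecord],
    topic_words: Sequence[tuple[str, float]] = (),
) -> TopicProfile:
    """Aggregate metadata frequencies over one topic's records.

    ``topic_words`` is passed through from the topic model (either
    extraction route); empty metadata lists simply yield empty tables.
    """
    if not records_in_topic:
        raise ValueError("a topic profile needs at least one record")
    years = [rec.year for rec in records_in_topic if rec.year is not None]
    return TopicProfile(
        topic_words=list(topic_words),
        mesh_freq=_freq_table([rec.mesh_terms for rec in records_in_topic]),
        chemical_freq=_freq_table([rec.chemicals for rec in records_in_topic]),
        keyword_freq=_freq_table([rec.keywords for rec in records_in_topic]),
        year_hist=dict(sorted(Counter(years).items())),
    )
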