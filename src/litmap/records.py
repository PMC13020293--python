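"""Publication records and the JSONL corpus cache.

A :class:`PublicationRecord` holds the fields mined from one PubMed
record: identifier, title, abstract/body text, publication year and the
three metadata lists (MeSH descriptors, chemical substances, author
keywords). Corpora are persisted as JSON Lines, one record per line,
which round-trips losslessly and preserves record order (the order of a
retrieved corpus is meaningful: it is the search engine's relevance
ranking).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

from pydantic import BaseModel, Field, field_validator

YEAR_MIN = 1800
YEAR_MAX = 2100


class PublicationRecord(BaseModel):
    """One parsed publication."""

    pub_id: str = Field(min_length=1)
    title: str = Field(min_length=1)
    body_text: str = ""
    year: Optional[int] = None
    mesh_terms: list[str] = Field(default_factory=list)
    chemicals: list[str] = Field(default_factory=list)
    keywords: list[str] = Field(default_factory=list)

    @field_validator("year")
    @classmethod
    def _year_in_range(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and not (YEAR_MIN <= v <= YEAR_MAX):
            raise ValueError(f"year {v} outside [{YEAR_MIN}, {YEAR_MAX}]")
        return v

    @property
    def text(self) -> str:
        """Title and body joined — the text fed to the embedder."""
        return f"{self.title} {self.body_text}".strip()


def write_jsonl(records: Iterable[PublicationRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.model_dump(), ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path) -> list[PublicationRecord]:
    records: list[PublicationRecord] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(PublicationRecord.model_validate(json.loads(line)))
    _check_unique_ids(records)
    return records


def _check_unique_ids(records: list[PublicationRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.pub_id in seen:
            raise ValueError(f"duplicate pub_id in corpus: {rec.pub_id!r}")
        seen.add(rec.pub_id)


def write_ranking(pub_ids: Iterable[str], path: str | Path) -> None:
    """Persist a reference ranking, one pub_id per line in rank order."""
    Path(path).write_text("\n".join(pub_ids) + "\n", encoding="utf-8")


def read_ranking(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
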