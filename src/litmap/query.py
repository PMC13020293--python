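"""Boolean search construction from alias groups.

Medical keywords usually carry synonyms ("POCD", "Postoperative
cognitive decline", ...). A search is therefore specified as up to two
*alias groups*: synonyms are OR-ed within a group and the groups are
AND-ed together, e.g.::

    (Maternal Pain OR Pain during pregnancy) AND (Postpartum depression OR Postnatal depression)

Designs with three or more groups are rejected at validation time rather
than truncated: the two-group limit is a deliberate interface
constraint, and :class:`SearchSpec` simply has no third slot.

``keyword_specificity`` summarises how specific a search's phrasing is,
as the mean phrase length in characters across all phrases of all
groups (internal spaces count; surrounding whitespace is stripped).
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, field_validator


class KeywordGroup(BaseModel):
    """A keyword and its aliases; at least one non-empty phrase."""

    phrases: list[str] = Field(min_length=1)

    @field_validator("phrases")
    @classmethod
    def _strip_and_check(cls, v: list[str]) -> list[str]:
        stripped = [p.strip() for p in v]
        if any(not p for p in stripped):
            raise ValueError("alias groups may not contain empty phrases")
        return stripped


class SearchSpec(BaseModel):
    """Up to two alias groups plus retrieval options."""

    group1: KeywordGroup
    group2: Optional[KeywordGroup] = None
    max_results: int = Field(default=100, ge=1)

    @classmethod
    def from_groups(
        cls, groups: list[list[str]], max_results: int = 100
    ) -> "SearchSpec":
        """Build a spec from raw phrase lists, enforcing the 2-group limit."""
        if not groups:
            raise ValueError("at least one alias group is required")
        if len(groups) > 2:
            raise ValueError(
                f"{len(groups)} alias groups given, but searches are limited "
                "to two groups by design; combine or drop the extra groups"
            )
        g1 = KeywordGroup(phrases=groups[0])
        g2 = KeywordGroup(phrases=groups[1]) if len(groups) == 2 else None
        return cls(group1=g1, group2=g2, max_results=max_results)

    def groups(self) -> list[KeywordGroup]:
        return [g for g in (self.group1, self.group2) if g is not None]

    def all_phrases(self) -> list[str]:
        return [p for g in self.groups() for p in g.phrases]


def build_boolean_query(spec: SearchSpec) -> str:
    """Render the boolean query: OR within groups, AND between them.

    Phrase order is preserved; phrases are neither quoted nor
    field-tagged, matching how a user would type them into the search
    portal.
    """
    clauses = ["(" + " OR ".join(g.phrases) + ")" for g in spec.groups()]
    return " AND ".join(clauses)


def keyword_specificity(spec: SearchSpec) -> float:
    """Mean number of characters per phrase, over all present groups.

    Character counting is Unicode code-point based and includes internal
    spaces. A single averaging step over the pooled phrases is used (not
    group-then-phrase averaging).
    """
    phrases = spec.all_phrases()
    return sum(len(p) for p in phrases) / len(phrases)
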