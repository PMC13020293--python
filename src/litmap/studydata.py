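"""Published reference inputs from an 18-participant expert labelling study.

Eighteen medical experts each ran one alias-group search and labelled
the suggested publications for relevance; the per-search user-agreed
relevance percentages and the search phrases they used are reproduced
here as inputs for the evaluation summaries (second group absent where
the participant searched with a single group).
"""

from __future__ import annotations

from .query import SearchSpec

# (group1 phrases, group2 phrases or None, user-agreed relevance %)
STUDY_SEARCHES: list[tuple[list[str], list[str] | None, float]] = [
    (["Maternal pain", "Pain during pregnancy"],
     ["Postpartum depression", "Postnatal depression"], 16.6),
    (["POCD", "Postoperative cognitive disorder", "Postoperative cognitive decline"],
     None, 40.0),
    (["Implanted cardio defibrillators"], ["Deactivation"], 65.0),
    (["Hypervolemia"], ["Cardiac Surgery"], 15.0),
    (["Urinary catheter discomfort"], ["Postoperative"], 65.0),
    (["Sevoflurane"], ["Ondansetron"], 35.0),
    (["Acute lymphoblastic leukemia"], ["Pediatric"], 33.3),
    (["Microbiome"], ["Brain-Gut"], 43.3),
    (["Ammonia"], ["Urinary tract infection"], 25.0),
    (["Transcranial magnetic stimulation"], ["Pain"], 56.6),
    (["Dissection"], ["Bovine"], 80.0),
    (["Propofol"], ["Remimazolam"], 40.0),
    (["Liver Failure"], ["Acidosis"], 56.6),
    (["PROM", "Preterm premature rupture of the membranes"], ["Antibiotics"], 50.0),
    (["Ondansetron"], ["Metoclopramide"], 100.0),
    (["Vital Sign"], ["Bleeding"], 90.0),
    (["Pancreatoduadenectomy"], ["Fluid"], 100.0),
    (["Heart", "Coronary"], ["Coronavirus", "COVID"], 30.0),
]


def study_relevance_percentages() -> list[float]:
    return [pct for _, _, pct in STUDY_SEARCHES]


def study_search_specs() -> list[SearchSpec]:
    return [
        SearchSpec.from_groups([g1] if g2 is None else [g1, g2])
        for g1, g2, _ in STUDY_SEARCHES
    ]
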