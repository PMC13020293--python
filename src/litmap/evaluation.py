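"""Evaluation statistics for suggestion quality and topic coherence.

The central relevance metric is *user-agreed relevance*: of the
publications a topic model suggested, what percentage did the reader
mark relevant — counting only topics the reader engaged with (at least
one relevant label), since an untouched topic says nothing about its
quality. Supporting analyses compare relevant publications against a
reference relevance ranking (their 1-based positions, mean, median and
a binned histogram), and relate per-search relevance to search volume
and keyword specificity via Spearman rank correlation.

Topic quality is measured with the C_v coherence measure: boolean
sliding windows over each document's token stream define word
probabilities; each of a topic's top-N words gets an NPMI context
vector against all N words; a word's score is the cosine of its vector
with the topic's summed vector, and the topic score is the mean over
words. C_v rewards topics whose words genuinely co-occur: two words
appearing in every window score exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy import stats

from .graph import LabelAssignment


@dataclass
class SearchEvaluation:
    """Per-search relevance bookkeeping."""

    search_id: str
    labelled_topics: dict[int, tuple[int, int]]  # topic -> (suggested, relevant)
    relevance_pct: float


def user_agreed_relevance(
    assignments: Sequence[LabelAssignment],
    suggestions: Mapping[int, Sequence[str]],
) -> Optional[float]:
    """Percentage of suggested publications marked relevant.

    Restricted to topics with at least one relevant label among their
    suggestions; the denominator is the total number suggested in those
    topics. Returns None when no topic received a relevant label (the
    metric is undefined, not zero). The value is unrounded; reporting
    rounds to one decimal.
    """
    if not suggestions:
        raise ValueError("suggestions must be non-empty")
    relevant_ids = {a.pub_id for a in assignments if a.relevant}
    total_suggested = 0
    total_relevant = 0
    for topic_id, pub_ids in suggestions.items():
        hits = sum(1 for pid in pub_ids if pid in relevant_ids)
        if hits == 0:
            continue
        total_suggested += len(pub_ids)
        total_relevant += hits
    if total_suggested == 0:
        return None
    return 100.0 * total_relevant / total_suggested


def relevance_summary(
    per_search_pcts: Sequence[float], threshold: float = 50.0
) -> tuple[float, float, int]:
    """(mean rounded to one decimal, minimum, count at/above threshold)."""
    if not per_search_pcts:
        raise ValueError("per_search_pcts must be non-empty")
    mean = round(float(np.mean(per_search_pcts)), 1)
    minimum = float(min(per_search_pcts))
    at_or_above = sum(1 for p in per_search_pcts if p >= threshold)
    return mean, minimum, at_or_above


@dataclass
class RankStats:
    positions: list[int]  # 1-based positions of found ids, ascending
    mean: Optional[float]
    median: Optional[float]
    histogram: dict[tuple[int, int], int]  # (lo, hi] bins, 1-based
    dropped: int  # relevant ids absent from the reference ranking


def reference_rank_stats(
    relevant_ids: Sequence[str],
    reference_ranking: Sequence[str],
    bin_width: int = 50,
) -> RankStats:
    """Where do the relevant publications sit in a reference ranking?

    Positions are 1-based (result lists are 1-based to users). Relevant
    ids absent from the ranking are dropped and counted separately. The
    histogram bins positions into [1, w], (w, 2w], ...
    """
    if not reference_ranking:
        raise ValueError("reference ranking must be non-empty")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    index = {pid: i + 1 for i, pid in enumerate(reference_ranking)}
    positions = sorted(index[pid] for pid in relevant_ids if pid in index)
    dropped = sum(1 for pid in relevant_ids if pid not in index)
    histogram: dict[tuple[int, int], int] = {}
    for pos in positions:
        bin_idx = (pos - 1) // bin_width
        key = (bin_idx * bin_width + 1, (bin_idx + 1) * bin_width)
        histogram[key] = histogram.get(key, 0) + 1
    return RankStats(
        positions=positions,
        mean=float(np.mean(positions)) if positions else None,
        median=float(np.median(positions)) if positions else None,
        histogram=histogram,
        dropped=dropped,
    )


@dataclass
class CorrelationReport:
    count_vs_relevance: list[tuple[float, float]]
    specificity_vs_relevance: list[tuple[float, float]]
    spearman_count: Optional[float]
    spearman_specificity: Optional[float]


def relevance_correlates(
    searches: Sequence[tuple[float, float, float]],
) -> CorrelationReport:
    """Relate relevance to result volume and keyword specificity.

    ``searches`` holds (result_count, specificity, relevance_pct) per
    search. Spearman rank correlation is used because neither
    relationship is assumed linear. A constant series has no rank
    ordering, so its coefficient is reported as None.
    """
    if len(searches) < 3:
        raise ValueError("need at least 3 searches to correlate")
    counts = [s[0] for s in searches]
    specs = [s[1] for s in searches]
    rels = [s[2] for s in searches]

    def rho(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
        if len(set(x)) < 2 or len(set(y)) < 2:
            return None
        return float(stats.spearmanr(x, y).statistic)

    return CorrelationReport(
        count_vs_relevance=list(zip(counts, rels)),
        specificity_vs_relevance=list(zip(specs, rels)),
        spearman_count=rho(counts, rels),
        spearman_specificity=rho(specs, rels),
    )


class CoherenceConfig(BaseModel):
    """C_v parameters: canonical defaults of the measure."""

    top_n_words: int = Field(default=10, ge=2)
    window_size: int = Field(default=110, ge=2)
    epsilon: float = Field(default=1e-12, gt=0)


def _sliding_windows(tokens: Sequence[str], size: int) -> list[frozenset[str]]:
    if len(tokens) <= size:
        return [frozenset(tokens)] if tokens else []
    return [frozenset(tokens[i : i + size]) for i in range(len(tokens) - size + 1)]


def cv_coherence(
    topic_word_sets: Sequence[Sequence[str]],
    tokenised_corpus: Sequence[Sequence[str]],
    config: Optional[CoherenceConfig] = None,
) -> tuple[list[Optional[float]], Optional[float]]:
    """Per-topic C_v scores and their mean.

    Word (and word-pair) probabilities are the fraction of boolean
    sliding windows containing the word(s); a document shorter than the
    window contributes a single window. A word absent from the corpus
    gets epsilon probability; a topic whose words are all absent has an
    undefined (None) score and is excluded from the mean.
    """
    config = config or CoherenceConfig()
    if not tokenised_corpus:
        raise ValueError("corpus must be non-empty")
    for words in topic_word_sets:
        if len(words) < 2:
            raise ValueError("every topic word set needs at least 2 words")

    windows: list[frozenset[str]] = []
    for doc in tokenised_corpus:
        windows.extend(_sliding_windows(doc, config.window_size))
    n_windows = len(windows)
    if n_windows == 0:
        raise ValueError("corpus contains no tokens")

    vocab = {w for words in topic_word_sets for w in words[: config.top_n_words]}
    occ: dict[str, int] = {w: 0 for w in vocab}
    pair_occ: dict[tuple[str, str], int] = {}
    for window in windows:
        present = [w for w in vocab if w in window]
        for i, wi in enumerate(present):
            occ[wi] += 1
            for wj in present[i + 1 :]:
                key = (wi, wj) if wi <= wj else (wj, wi)
                pair_occ[key] = pair_occ.get(key, 0) + 1

    eps = config.epsilon

    def p_word(w: str) -> float:
        p = occ[w] / n_windows
        return p if p > 0 else eps

    def p_pair(a: str, b: str) -> float:
        if a == b:
            return p_word(a)
        key = (a, b) if a <= b else (b, a)
        return pair_occ.get(key, 0) / n_windows

    def npmi(a: str, b: str) -> float:
        joint = p_pair(a, b)
        num = math.log((joint + eps) / (p_word(a) * p_word(b)))
        den = -math.log(joint + eps)
        return num / den

    scores: list[Optional[float]] = []
    for words in topic_word_sets:
        top = list(dict.fromkeys(words[: config.top_n_words]))
        if all(occ[w] == 0 for w in top):
            scores.append(None)
            continue
        vectors = np.array([[npmi(wi, wj) for wj in top] for wi in top])
        summed = vectors.sum(axis=0)
        word_scores = []
        for row in vectors:
            denom = np.linalg.norm(row) * np.linalg.norm(summed)
            word_scores.append(float(np.dot(row, summed) / denom) if denom > 0 else 0.0)
        scores.append(float(np.mean(word_scores)))

    defined = [s for s in scores if s is not None]
    return scores, (float(np.mean(defined)) if defined else None)
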