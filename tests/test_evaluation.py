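"""Relevance metrics, rank analysis, correlations and C_v coherence."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from litmap import (
    CoherenceConfig,
    LabelAssignment,
    cv_coherence,
    reference_rank_stats,
    relevance_correlates,
    relevance_summary,
    user_agreed_relevance,
)
from litmap.studydata import study_relevance_percentages


def labels_for(ids, relevant_ids):
    return [
        LabelAssignment(pub_id=i, relevant=i in relevant_ids, user_label="t")
        for i in ids
    ]


class TestUserAgreedRelevance:
    def test_direct_ratio_single_topic(self):
        suggestions = {0: [str(i) for i in range(10)]}
        pct = user_agreed_relevance(labels_for(suggestions[0], {"0", "1", "2"}), suggestions)
        assert pct == pytest.approx(30.0)

    def test_unlabelled_topic_excluded_from_denominator(self):
        suggestions = {0: [f"a{i}" for i in range(10)], 1: [f"b{i}" for i in range(10)]}
        labels = labels_for(suggestions[0], {"a0", "a1", "a2", "a3"})
        assert user_agreed_relevance(labels, suggestions) == pytest.approx(40.0)

    def test_no_relevant_topic_is_undefined(self):
        suggestions = {0: ["1", "2"]}
        assert user_agreed_relevance([], suggestions) is None

    def test_matches_counting_oracle_on_random_labellings(self, rng):
        suggestions = {t: [f"{t}-{i}" for i in range(10)] for t in range(4)}
        all_ids = [pid for pids in suggestions.values() for pid in pids]
        for _ in range(50):
            chosen = {pid for pid in all_ids if rng.random() < 0.3}
            got = user_agreed_relevance(labels_for(all_ids, chosen), suggestions)
            num = den = 0
            for pids in suggestions.values():
                hits = len([p for p in pids if p in chosen])
                if hits:
                    num += hits
                    den += len(pids)
            expected = 100 * num / den if den else None
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)

    def test_in_range_and_monotone_in_added_relevant_label(self):
        suggestions = {0: [str(i) for i in range(10)]}
        pcts = [
            user_agreed_relevance(labels_for(suggestions[0], set(map(str, range(k + 1)))), suggestions)
            for k in range(10)
        ]
        assert all(0 <= p <= 100 for p in pcts)
        assert pcts == sorted(pcts)


class TestRelevanceSummary:
    def test_study_table_headline_numbers(self):
        mean, minimum, at_least_half = relevance_summary(study_relevance_percentages(), 50.0)
        assert mean == 52.3
        assert minimum == 15.0
        assert at_least_half == 9

    def test_singleton(self):
        assert relevance_summary([40.0], 50.0) == (40.0, 40.0, 0)

    def test_mean_between_min_and_max(self, rng):
        for _ in range(100):
            pcts = list(rng.uniform(0, 100, size=rng.integers(1, 20)))
            mean, minimum, count = relevance_summary(pcts, 50.0)
            # mean is reported rounded to one decimal
            assert minimum - 0.05 <= mean <= max(pcts) + 0.05
            assert minimum == min(pcts)
            assert count == sum(1 for p in pcts if p >= 50.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            relevance_summary([], 50.0)


class TestReferenceRankStats:
    def test_tiny_list_positions(self):
        ranking = [str(i) for i in range(1, 11)]
        out = reference_rank_stats(["1", "3"], ranking)
        assert out.positions == [1, 3]
        assert out.mean == 2.0 and out.median == 2.0

    def test_absent_id_dropped_and_counted(self):
        out = reference_rank_stats(["1", "zzz"], ["1", "2"])
        assert out.positions == [1] and out.dropped == 1

    def test_empty_relevant_set_gives_empty_stats(self):
        out = reference_rank_stats([], ["1", "2"])
        assert out.positions == [] and out.mean is None and out.median is None

    def test_matches_index_scan_oracle_on_planted_ranking(self, rng):
        ranking = [f"p{i}" for i in range(500)]
        relevant = list(rng.choice(ranking, size=25, replace=False))
        out = reference_rank_stats(relevant, ranking, bin_width=100)
        oracle_positions = sorted(ranking.index(pid) + 1 for pid in relevant)
        assert out.positions == oracle_positions
        assert out.mean == pytest.approx(np.mean(oracle_positions))
        assert out.median == pytest.approx(np.median(oracle_positions))
        oracle_hist: dict[tuple[int, int], int] = {}
        for pos in oracle_positions:
            lo = ((pos - 1) // 100) * 100 + 1
            oracle_hist[(lo, lo + 99)] = oracle_hist.get((lo, lo + 99), 0) + 1
        assert out.histogram == oracle_hist
        assert sum(out.histogram.values()) == len(out.positions)


class TestCorrelates:
    def test_monotone_decreasing_gives_minus_one(self):
        searches = [(float(n), 5.0 + n, 100.0 - n) for n in range(10)]
        out = relevance_correlates(searches)
        assert out.spearman_count == pytest.approx(-1.0)

    def test_independent_series_near_zero(self, rng):
        rels = rng.permutation(200).astype(float)
        searches = [(float(i), float(i % 7), rels[i]) for i in range(200)]
        out = relevance_correlates(searches)
        assert abs(out.spearman_count) < 0.2

    def test_tie_heavy_series_matches_average_rank_oracle(self, rng):
        counts = list(rng.integers(0, 4, size=30).astype(float))
        rels = list(rng.integers(0, 3, size=30).astype(float))
        searches = [(c, 1.0 + i % 2, r) for i, (c, r) in enumerate(zip(counts, rels))]
        out = relevance_correlates(searches)
        # oracle: Pearson on average-ranks
        def avg_ranks(x):
            order = sorted(range(len(x)), key=lambda i: x[i])
            ranks = [0.0] * len(x)
            i = 0
            while i < len(order):
                j = i
                while j < len(order) and x[order[j]] == x[order[i]]:
                    j += 1
                mean_rank = (i + j + 1) / 2  # 1-based average rank of the tie block
                for idx in order[i:j]:
                    ranks[idx] = mean_rank
                i = j
            return ranks

        rx, ry = avg_ranks(counts), avg_ranks(rels)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert out.spearman_count == pytest.approx(expected, abs=1e-12)

    def test_constant_series_reported_undefined(self):
        searches = [(1.0, 2.0, 50.0), (1.0, 3.0, 60.0), (1.0, 4.0, 70.0)]
        out = relevance_correlates(searches)
        assert out.spearman_count is None
        assert out.spearman_specificity is not None

    def test_fewer_than_three_searches_rejected(self):
        with pytest.raises(ValueError):
            relevance_correlates([(1.0, 2.0, 3.0)])


def brute_force_cv(topic_words, docs, window, eps=1e-12):
    """Independent C_v: materialise every window and every NPMI term."""
    windows = []
    for doc in docs:
        if len(doc) <= window:
            windows.append(set(doc))
        else:
            for i in range(len(doc) - window + 1):
                windows.append(set(doc[i : i + window]))
    n = len(windows)

    def p(words):
        count = sum(1 for w in windows if all(x in w for x in words))
        return count / n

    def p1(w):
        v = p([w])
        return v if v > 0 else eps

    def npmi(a, b):
        joint = p1(a) if a == b else p([a, b])
        return math.log((joint + eps) / (p1(a) * p1(b))) / (-math.log(joint + eps))

    scores = []
    for words in topic_words:
        vecs = [[npmi(wi, wj) for wj in words] for wi in words]
        summed = [sum(col) for col in zip(*vecs)]
        per_word = []
        for v in vecs:
            dot = sum(a * b for a, b in zip(v, summed))
            nv = math.sqrt(sum(a * a for a in v))
            ns = math.sqrt(sum(a * a for a in summed))
            per_word.append(dot / (nv * ns) if nv * ns > 0 else 0.0)
        scores.append(sum(per_word) / len(per_word))
    return scores


class TestCvCoherence:
    def test_perfectly_cooccurring_pair_scores_one(self):
        docs = [["aa", "bb", "cc"], ["aa", "bb", "dd"], ["aa", "bb"]]
        scores, mean = cv_coherence([["aa", "bb"]], docs, CoherenceConfig(window_size=3))
        assert scores[0] == pytest.approx(1.0, abs=1e-9)
        assert mean == pytest.approx(1.0, abs=1e-9)

    def test_single_short_document_defines_one_window(self):
        docs = [["aa", "bb"]]
        scores, mean = cv_coherence([["aa", "bb"]], docs, CoherenceConfig(window_size=110))
        assert scores[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_full_enumeration_oracle_on_toy_corpus(self):
        docs = [
            ["aa", "bb", "cc", "dd", "aa"],
            ["bb", "cc", "ee", "aa"],
            ["dd", "ee", "aa", "bb", "cc", "dd"],
            ["cc", "cc", "bb"],
            ["ee", "dd", "aa"],
        ]
        topics = [["aa", "bb", "cc"], ["cc", "dd", "ee"]]
        config = CoherenceConfig(window_size=3, top_n_words=3)
        scores, mean = cv_coherence(topics, docs, config)
        expected = brute_force_cv(topics, docs, window=3)
        for got, want in zip(scores, expected):
            assert got == pytest.approx(want, abs=1e-9)
        assert mean == pytest.approx(np.mean(expected), abs=1e-9)

    def test_invariant_to_document_order(self):
        docs = [["aa", "bb", "cc"], ["cc", "dd"], ["aa", "dd", "bb"]]
        topics = [["aa", "bb"], ["cc", "dd"]]
        config = CoherenceConfig(window_size=2)
        for perm in itertools.permutations(docs):
            scores, _ = cv_coherence(topics, list(perm), config)
            base, _ = cv_coherence(topics, docs, config)
            assert scores == pytest.approx(base)

    def test_never_cooccurring_replacement_does_not_increase_score(self):
        docs = [["aa", "bb", "cc"]] * 4 + [["zz", "yy"]] * 2
        config = CoherenceConfig(window_size=3)
        coherent, _ = cv_coherence([["aa", "bb"]], docs, config)
        broken, _ = cv_coherence([["aa", "zz"]], docs, config)
        assert broken[0] <= coherent[0] + 1e-12

    def test_all_absent_topic_reported_undefined(self):
        docs = [["aa", "bb"]]
        scores, mean = cv_coherence(
            [["qq", "rr"], ["aa", "bb"]], docs, CoherenceConfig(window_size=2)
        )
        assert scores[0] is None
        assert scores[1] is not None and mean == scores[1]

    def test_word_set_smaller_than_two_rejected(self):
        with pytest.raises(ValueError):
            cv_coherence([["aa"]], [["aa", "bb"]], CoherenceConfig())
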