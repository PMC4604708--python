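"""Study networks, evaluation reports, missed-study classes, medians."""

from __future__ import annotations

import random

import numpy as np
import pytest

from cocites import (
    ArticleRecord,
    CitationCorpus,
    aggregate_reports,
    build_study_network,
    classify_missed,
    evaluate_search,
    median_rounded,
    percentage,
    report_from_counts,
    round_half_away,
)

from conftest import bf_components, build_random_corpus


# ---------------------------------------------------------------------------
# Study networks
# ---------------------------------------------------------------------------


def _study_corpus(edges: dict[str, list[str]], studies):
    records = [
        ArticleRecord(article_id=s, refkey=f"k{s}", cited_refs=[f"k{t}" for t in edges.get(s, [])])
        for s in studies
    ]
    return CitationCorpus(records), {f"k{s}" for s in studies}


def test_network_singleton_component():
    corpus, studies = _study_corpus({"a": ["b"]}, ["a", "b", "c"])
    net = build_study_network(corpus, studies)
    assert sorted(map(sorted, net.components)) == [["ka", "kb"], ["kc"]]
    assert net.n_disconnected == 1


def test_network_chain_single_component():
    corpus, studies = _study_corpus({"a": ["b"], "b": ["c"]}, ["a", "b", "c"])
    net = build_study_network(corpus, studies)
    assert len(net.components) == 1 and net.n_disconnected == 0


def test_network_non_indexed_study_is_isolated():
    corpus, studies = _study_corpus({"a": ["b"]}, ["a", "b"])
    net = build_study_network(corpus, studies | {"kGhost"})
    assert {"kGhost"} in net.components
    assert net.n_disconnected == 1


def test_network_empty_study_set_raises():
    corpus, _ = _study_corpus({}, ["a"])
    with pytest.raises(ValueError):
        build_study_network(corpus, set())


@pytest.mark.parametrize("seed", [31, 32, 33])
def test_components_match_brute_force_closure(seed):
    corpus = build_random_corpus(seed=seed, n_articles=60)
    rng = random.Random(seed)
    studies = {corpus.refkey_of_article[f"A{i:03d}"] for i in rng.sample(range(60), 25)}
    net = build_study_network(corpus, studies)
    expected = bf_components(corpus, studies)
    assert sorted(map(sorted, net.components)) == sorted(map(sorted, expected))


# ---------------------------------------------------------------------------
# Rounding and percentages
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "num,den,expected",
    [
        (10, 12, 83),     # retrieval: ten of twelve gold studies found
        (967, 9151, 11),  # screening: 967 candidates vs 9,151 keyword hits
        (8, 10, 80),
        (62, 8646, 1),
        (109, 17500, 1),  # 0.62 rounds up to 1
        (780, 784, 99),   # 99.49 rounds down
        (3234, 784, 413), # exactly 412.5 rounds away from zero
        (1, 200, 1),
        (0, 5, 0),
    ],
)
def test_percentage_rounding(num, den, expected):
    assert percentage(num, den) == expected


def test_round_half_away_negative():
    assert round_half_away(-2.5) == -3
    assert round_half_away(2.5) == 3


def test_median_even_length_rule():
    assert median_rounded([62, 111, 120, 173, 186, 224, 780, 913, 1719, 1924]) == 205
    assert median_rounded([1, 2]) == 2  # 1.5 rounds away from zero
    assert median_rounded([7]) == 7


@pytest.mark.parametrize("seed", range(10))
def test_median_matches_numpy_oracle(seed):
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 1000, size=int(rng.integers(1, 40))).tolist()
    assert median_rounded(values) == round_half_away(float(np.median(values)))


# ---------------------------------------------------------------------------
# Evaluation reports
# ---------------------------------------------------------------------------


def test_evaluate_published_style_counts():
    report = report_from_counts(
        n_screened=967, n_screened_original=9151, n_included=12, n_retrieved=10
    )
    assert report.retrieval_pct == 83 and report.screening_pct == 11


def test_evaluate_perfect_retrieval():
    gold = {"a", "b", "c"}
    report = evaluate_search(gold | {"extra"}, gold, n_screened_original=100)
    assert report.retrieval_pct == 100 and report.missed == []


def test_evaluate_with_sets():
    selected = {f"s{i}" for i in range(62)} | {f"g{i}" for i in range(5)}
    gold = {f"g{i}" for i in range(10)}
    report = evaluate_search(selected, gold, n_screened_original=8646)
    assert report.n_screened == 67
    assert report.n_retrieved == 5
    assert report.retrieval_pct == 50
    assert report.n_retrieved + len(report.missed) == report.n_included


def test_evaluate_empty_gold_raises():
    with pytest.raises(ValueError):
        evaluate_search({"a"}, set(), 10)


def test_retrieval_monotone_in_selection():
    gold = {f"g{i}" for i in range(8)}
    rng = random.Random(2)
    selection: set[str] = set()
    last = 0
    pool = list(gold) + [f"n{i}" for i in range(30)]
    rng.shuffle(pool)
    for key in pool:
        selection.add(key)
        pct = evaluate_search(selection, gold, 100).retrieval_pct
        assert pct >= last
        last = pct


# ---------------------------------------------------------------------------
# Missed-study classification
# ---------------------------------------------------------------------------


def _metadata_corpus():
    records = [
        ArticleRecord(article_id="old", refkey="kold", year=1969, language="English"),
        ArticleRecord(article_id="abs", refkey="kabs", year=1969, doc_type="abstract"),
        ArticleRecord(article_id="de", refkey="kde", year=1990, language="German"),
        ArticleRecord(article_id="new", refkey="knew", year=2015, language="English"),
        ArticleRecord(article_id="plain", refkey="kplain", year=1990, language="English"),
    ]
    return CitationCorpus(records)


def test_classify_categories_and_precedence():
    corpus = _metadata_corpus()
    out = dict(
        classify_missed(["kold", "kabs", "kde", "knew", "kplain", "kmissing"], corpus, 2015)
    )
    assert out == {
        "kold": "old_pre1975",
        "kabs": "abstract",  # abstract wins over pre-1975
        "kde": "non_english",
        "knew": "recent",
        "kplain": "other",
        "kmissing": "other",  # not indexed anywhere
    }


def test_classified_counts_match_planted_fixture():
    """14 missed studies with planted attributes: counts per class recover the plant."""
    plant = {"abstract": 2, "non_english": 3, "old_pre1975": 4, "recent": 1, "other": 4}
    records = []
    i = 0
    for category, n in plant.items():
        for _ in range(n):
            kwargs = {"year": 1990, "language": "English", "doc_type": "article"}
            if category == "abstract":
                kwargs["doc_type"] = "abstract"
            elif category == "non_english":
                kwargs["language"] = "French"
            elif category == "old_pre1975":
                kwargs["year"] = 1960
            elif category == "recent":
                kwargs["year"] = 2014
            records.append(ArticleRecord(article_id=f"m{i}", refkey=f"km{i}", **kwargs))
            i += 1
    corpus = CitationCorpus(records)
    out = classify_missed([f"km{j}" for j in range(i)], corpus, 2014)
    counts: dict[str, int] = {}
    for _, category in out:
        counts[category] = counts.get(category, 0) + 1
    assert counts == plant


def test_missed_category_totals_balance():
    corpus = _metadata_corpus()
    gold = {"kold", "kabs", "kde", "knew", "kplain"}
    report = evaluate_search({"kplain"}, gold, 50, corpus=corpus, search_year=2015)
    assert report.n_retrieved + len(report.missed) == report.n_included


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def test_aggregate_single_report_is_identity():
    report = report_from_counts(120, 1154, 5, 5)
    summary = aggregate_reports([report])
    assert summary.median_screened == 120
    assert summary.median_retrieval_pct == 100
    assert summary.median_screening_pct == 10


def test_aggregate_matches_sort_based_oracle():
    rng = random.Random(9)
    for _ in range(100):
        reports = [
            report_from_counts(
                n_screened=rng.randint(0, 2000),
                n_screened_original=rng.randint(1, 20000),
                n_included=(n_inc := rng.randint(1, 40)),
                n_retrieved=rng.randint(0, n_inc),
            )
            for _ in range(rng.randint(1, 15))
        ]
        summary = aggregate_reports(reports)

        def oracle(values):
            ordered = sorted(values)
            mid = len(ordered) // 2
            if len(ordered) % 2:
                raw = float(ordered[mid])
            else:
                raw = (ordered[mid - 1] + ordered[mid]) / 2.0
            return round_half_away(raw)

        assert summary.median_screened == oracle([r.n_screened for r in reports])
        assert summary.median_retrieved == oracle([r.n_retrieved for r in reports])
        assert summary.median_retrieval_pct == oracle(
            [100.0 * r.n_retrieved / r.n_included for r in reports]
        )
        assert summary.median_screening_pct == oracle(
            [100.0 * r.n_screened / r.n_screened_original for r in reports]
        )
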