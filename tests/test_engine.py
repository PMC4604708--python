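"""Co-citation collection, filtering and counting."""

from __future__ import annotations

import pytest

from cocites import (
    ArticleRecord,
    CitationCorpus,
    SeedSet,
    collect_citing_articles,
    count_cocitations,
    filter_citing_articles,
    run_cocitation_search,
    seed_refkeys,
)

from conftest import bf_collect_citers, bf_count_cocitations, build_random_corpus


def test_collect_single_seed(toy_corpus):
    seeds = SeedSet(known_ids={"S1"})
    assert collect_citing_articles(toy_corpus, seeds) == {"A", "B"}


def test_collect_union_not_multiset(toy_corpus):
    """An article citing two knowns contributes one reference list."""
    seeds = SeedSet(known_ids={"S1", "S2"})
    assert collect_citing_articles(toy_corpus, seeds) == {"A", "B", "C"}


def test_collect_unknown_seed_raises(toy_corpus):
    with pytest.raises(KeyError, match="NOPE"):
        collect_citing_articles(toy_corpus, SeedSet(known_ids={"NOPE"}))


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_collect_matches_brute_force(seed):
    corpus = build_random_corpus(seed=seed, n_articles=50)
    seeds = SeedSet(known_ids={"A003", "A017"})
    expected = bf_collect_citers(corpus, seed_refkeys(corpus, seeds))
    assert collect_citing_articles(corpus, seeds) == expected


def test_filter_cutoff_is_strict_and_exclusions_apply():
    records = [
        ArticleRecord(article_id="S", refkey="kS"),
        ArticleRecord(article_id="A", refkey="kA", year=2010, cited_refs=["kS"]),
        ArticleRecord(article_id="B", refkey="kB", year=2014, cited_refs=["kS"]),
        ArticleRecord(article_id="C", refkey="kC", year=2015, cited_refs=["kS"]),
        ArticleRecord(article_id="M", refkey="kM", year=2014, cited_refs=["kS"]),
    ]
    corpus = CitationCorpus(records)
    seeds = SeedSet(known_ids={"S"}, exclusion_ids={"M"}, date_cutoff_year=2014)
    citing = collect_citing_articles(corpus, seeds)
    assert filter_citing_articles(citing, corpus, seeds) == {"A", "B"}


def test_filter_retains_unknown_year(caplog):
    records = [
        ArticleRecord(article_id="S", refkey="kS"),
        ArticleRecord(article_id="A", refkey="kA", year=None, cited_refs=["kS"]),
    ]
    corpus = CitationCorpus(records)
    seeds = SeedSet(known_ids={"S"}, date_cutoff_year=2000)
    with caplog.at_level("WARNING", logger="cocites"):
        kept = filter_citing_articles({"A"}, corpus, seeds)
    assert kept == {"A"}
    assert any("unknown year" in m for m in caplog.messages)


def test_filter_without_cutoff_or_exclusions_is_identity(toy_corpus):
    seeds = SeedSet(known_ids={"S1"})
    citing = collect_citing_articles(toy_corpus, seeds)
    assert filter_citing_articles(citing, toy_corpus, seeds) == citing


def test_count_hand_example():
    records = [
        ArticleRecord(article_id="S", refkey="kS"),
        ArticleRecord(article_id="A", refkey="kA", cited_refs=["kS", "kX", "kY"]),
        ArticleRecord(article_id="B", refkey="kB", cited_refs=["kS", "kX"]),
    ]
    corpus = CitationCorpus(records)
    seeds = SeedSet(known_ids={"S"})
    table = count_cocitations(corpus, {"A", "B"}, seeds)
    assert table.counts() == {"kX": 2, "kY": 1}
    assert table.n_citing == 2
    by_key = {r.refkey: r for r in table.records}
    assert by_key["kX"].j_index == 100.0
    assert by_key["kY"].j_index == 50.0
    assert "kS" not in table.counts()


def test_duplicate_within_one_reference_list_counts_once():
    records = [
        ArticleRecord(article_id="S", refkey="kS"),
        ArticleRecord(article_id="A", refkey="kA", cited_refs=["kS", "kX", "kX"]),
    ]
    corpus = CitationCorpus(records)
    table = count_cocitations(corpus, {"A"}, SeedSet(known_ids={"S"}))
    assert table.counts() == {"kX": 1}


def test_empty_citing_set_gives_empty_table(toy_corpus):
    table = count_cocitations(toy_corpus, set(), SeedSet(known_ids={"S1"}))
    assert table.records == [] and table.n_citing == 0


def test_toy_search_matches_hand_count(toy_corpus):
    """Two knowns, three citers: kX co-cited by all three, kY and kZ once."""
    table = run_cocitation_search(toy_corpus, SeedSet(known_ids={"S1", "S2"}))
    assert table.counts() == {"kX": 3, "kY": 1, "kZ": 1}
    assert [r.refkey for r in table.records] == ["kX", "kY", "kZ"]
    assert [r.rank for r in table.records] == [1, 2, 3]


def test_seeds_with_zero_citers_give_empty_table():
    records = [
        ArticleRecord(article_id="S", refkey="kS"),
        ArticleRecord(article_id="A", refkey="kA", cited_refs=["kB"]),
    ]
    corpus = CitationCorpus(records)
    table = run_cocitation_search(corpus, SeedSet(known_ids={"S"}))
    assert len(table) == 0 and table.n_citing == 0


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_count_matches_brute_force(seed):
    corpus = build_random_corpus(seed=seed, n_articles=40)
    seeds = SeedSet(known_ids={"A001", "A002"})
    table = run_cocitation_search(corpus, seeds)
    skeys = seed_refkeys(corpus, seeds)
    citing = bf_collect_citers(corpus, skeys)
    assert table.counts() == bf_count_cocitations(corpus, citing, skeys)


def test_composition_equals_stagewise(toy_corpus):
    seeds = SeedSet(known_ids={"S1", "S2"})
    table = run_cocitation_search(toy_corpus, seeds)
    citing = filter_citing_articles(collect_citing_articles(toy_corpus, seeds), toy_corpus, seeds)
    manual = count_cocitations(toy_corpus, citing, seeds)
    assert table.counts() == manual.counts() and table.n_citing == manual.n_citing


def test_counts_bounded_by_n_citing():
    for seed in range(6):
        corpus = build_random_corpus(seed=seed, n_articles=50)
        table = run_cocitation_search(corpus, SeedSet(known_ids={"A000"}))
        for r in table.records:
            assert 1 <= r.cocitation_count <= table.n_citing


def test_monotone_under_corpus_growth():
    """Adding a citing article never decreases an existing candidate's count."""
    corpus = build_random_corpus(seed=21, n_articles=30)
    seeds = SeedSet(known_ids={"A000"})
    before = run_cocitation_search(corpus, seeds).counts()
    extra = ArticleRecord(
        article_id="NEW", refkey="knew",
        cited_refs=[corpus.refkey_of_article["A000"], "work 005|1995|j test", "brand new key"],
    )
    corpus.add(extra)
    after = run_cocitation_search(corpus, seeds).counts()
    for key, count in before.items():
        assert after[key] >= count


def test_insertion_order_does_not_change_table():
    corpus = build_random_corpus(seed=9, n_articles=40)
    articles = list(corpus)
    shuffled = CitationCorpus(reversed(articles))
    seeds = SeedSet(known_ids={"A004"})
    t1 = run_cocitation_search(corpus, seeds)
    t2 = run_cocitation_search(shuffled, seeds)
    assert [(r.refkey, r.cocitation_count, r.rank) for r in t1.records] == [
        (r.refkey, r.cocitation_count, r.rank) for r in t2.records
    ]


def test_seedset_validation():
    with pytest.raises(ValueError):
        SeedSet(known_ids=set())
    with pytest.raises(ValueError):
        SeedSet(known_ids={"A"}, exclusion_ids={"A"})
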