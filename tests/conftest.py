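"""Shared fixtures: small constructed corpora and brute-force oracles.

The oracles deliberately re-derive everything from the articles' reference
lists with naive double loops, independent of the maps and counters the
package maintains, so agreement is a real check.
"""

from __future__ import annotations

import random

import pytest

from cocites import ArticleRecord, CitationCorpus, RefKey


def build_random_corpus(
    seed: int,
    n_articles: int = 40,
    n_external: int = 12,
    p_ref: float = 0.12,
    p_dup: float = 0.2,
    p_year_missing: float = 0.1,
) -> CitationCorpus:
    """An arbitrary citation structure: internal and external cited works,
    occasional duplicated entries within one reference list, some unknown years."""
    rng = random.Random(seed)
    keys = [f"work {i:03d}|{1990 + i % 20}|j test" for i in range(n_articles)]
    external = [f"ext {i:02d}|1980|j old" for i in range(n_external)]
    records = []
    for i in range(n_articles):
        refs: list[RefKey] = []
        for j, key in enumerate(keys):
            if j != i and rng.random() < p_ref:
                refs.append(key)
                if rng.random() < p_dup:
                    refs.append(key)
        for key in external:
            if rng.random() < 0.08:
                refs.append(key)
        year = None if rng.random() < p_year_missing else 1990 + i % 20
        records.append(
            ArticleRecord(
                article_id=f"A{i:03d}",
                first_author_surname=f"AU{i:03d}",
                year=year,
                source="J TEST",
                refkey=keys[i],
                cited_refs=refs,
                language="English",
            )
        )
    return CitationCorpus(records)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def bf_cited_by(corpus: CitationCorpus) -> dict[RefKey, set[str]]:
    out: dict[RefKey, set[str]] = {}
    for article in corpus:
        for key in article.cited_refs:
            out.setdefault(key, set()).add(article.article_id)
    return out


def bf_collect_citers(corpus: CitationCorpus, seed_keys: set[RefKey]) -> set[str]:
    return {
        a.article_id
        for a in corpus
        if any(k in seed_keys for k in a.cited_refs)
    }


def bf_count_cocitations(
    corpus: CitationCorpus, citing: set[str], seed_keys: set[RefKey]
) -> dict[RefKey, int]:
    """Double loop over (citing article, reference) with per-citer dedup."""
    counts: dict[RefKey, int] = {}
    for article_id in citing:
        seen: set[RefKey] = set()
        for key in corpus.articles[article_id].cited_refs:
            if key in seen or key in seed_keys or key == "unusable":
                continue
            seen.add(key)
            counts[key] = counts.get(key, 0) + 1
    return counts


def bf_direct_links(
    corpus: CitationCorpus, query: set[RefKey]
) -> dict[RefKey, int]:
    """Distinct query members linked to each candidate in either direction."""
    links: dict[RefKey, set[RefKey]] = {}
    for member in query:
        member_article = corpus.article_of_refkey.get(member)
        member_refs = set(corpus.articles[member_article].cited_refs) if member_article else set()
        for article in corpus:
            candidate = article.refkey
            if candidate in query:
                continue
            if member in article.cited_refs or candidate in member_refs:
                links.setdefault(candidate, set()).add(member)
        # candidates that are reference-only (no indexed article)
        for key in member_refs:
            if key not in query and key not in corpus.article_of_refkey:
                links.setdefault(key, set()).add(member)
    return {k: len(v) for k, v in links.items() if k != "unusable"}


def bf_components(corpus: CitationCorpus, studies: set[RefKey]) -> list[set[RefKey]]:
    """Connected components by repeated closure over an adjacency double loop."""
    adjacency = {s: set() for s in studies}
    for a in studies:
        article_id = corpus.article_of_refkey.get(a)
        refs = set(corpus.articles[article_id].cited_refs) if article_id else set()
        for b in studies:
            if a != b and b in refs:
                adjacency[a].add(b)
                adjacency[b].add(a)
    components = []
    remaining = set(studies)
    while remaining:
        start = remaining.pop()
        component = {start}
        frontier = [start]
        while frontier:
            node = frontier.pop()
            for neighbor in adjacency[node]:
                if neighbor not in component:
                    component.add(neighbor)
                    frontier.append(neighbor)
        remaining -= component
        components.append(component)
    return components


@pytest.fixture
def toy_corpus() -> CitationCorpus:
    """Two known studies, three citing articles, hand-countable co-citations."""
    records = [
        ArticleRecord(article_id="S1", refkey="kS1", year=2005),
        ArticleRecord(article_id="S2", refkey="kS2", year=2006),
        ArticleRecord(article_id="A", refkey="kA", year=2010, cited_refs=["kS1", "kX", "kY"]),
        ArticleRecord(article_id="B", refkey="kB", year=2011, cited_refs=["kS1", "kS2", "kX"]),
        ArticleRecord(article_id="C", refkey="kC", year=2012, cited_refs=["kS2", "kX", "kZ"]),
    ]
    return CitationCorpus(records)
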