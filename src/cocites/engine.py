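"""Co-citation ranking: from known seed articles to a ranked candidate table.

The first-stage search walks the citation graph one step forward and one
step back: every article that cites a known (seed) article contributes its
whole reference list, and each work on those lists is a candidate whose
co-citation count is the number of *distinct* citing articles that list
it.  The count therefore ranges from 1 to the number of citing articles,
and the j-index expresses it as a percentage of that number.

A citer of several seeds contributes one reference list (the citing sets
are unioned), and a work listed twice in one reference list counts once.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Optional

from .io import CitationCorpus, RefKey, UNUSABLE_KEY

logger = logging.getLogger("cocites")


@dataclass
class SeedSet:
    """The articles known at the start of the search, plus run filters.

    ``exclusion_ids`` removes specific citing articles (typically the
    review the gold standard came from); ``date_cutoff_year`` removes
    citing articles published strictly after that year.
    """

    known_ids: set[str]
    exclusion_ids: set[str] = field(default_factory=set)
    date_cutoff_year: Optional[int] = None

    def __post_init__(self) -> None:
        self.known_ids = set(self.known_ids)
        self.exclusion_ids = set(self.exclusion_ids)
        if not self.known_ids:
            raise ValueError("seed set needs at least one known article")
        overlap = self.known_ids & self.exclusion_ids
        if overlap:
            raise ValueError(f"articles both known and excluded: {sorted(overlap)}")


@dataclass
class CoCitationRecord:
    """One candidate work: co-citation count, j-index and rank."""

    refkey: RefKey
    cocitation_count: int
    j_index: float
    rank: int


@dataclass
class CoCitationTable:
    """Ranked candidates for one seed set.

    ``records`` is sorted by descending count, ties broken by ascending
    key text, so output is deterministic.  Seed articles' own keys are
    excluded from the records and reported via ``seed_keys``.
    """

    records: list[CoCitationRecord]
    n_citing: int
    seed_keys: set[RefKey]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def counts(self) -> dict[RefKey, int]:
        return {r.refkey: r.cocitation_count for r in self.records}

    def size_at_threshold(self, k: int) -> int:
        """Number of candidates co-cited at least ``k`` times."""
        return sum(1 for r in self.records if r.cocitation_count >= k)


def seed_refkeys(corpus: CitationCorpus, seeds: SeedSet) -> set[RefKey]:
    keys = set()
    for article_id in seeds.known_ids:
        if article_id not in corpus.articles:
            raise KeyError(f"unknown seed article id: {article_id!r}")
        keys.add(corpus.refkey_of_article[article_id])
    return keys


def collect_citing_articles(corpus: CitationCorpus, seeds: SeedSet) -> set[str]:
    """All articles whose reference list contains any seed article's key.

    An article citing two seeds appears once: the per-seed citer sets are
    unioned, which is why two seeds cited 50 times each yield *up to* 100
    reference lists, not exactly 100.
    """
    citing: set[str] = set()
    for key in seed_refkeys(corpus, seeds):
        citing |= corpus.cited_by.get(key, set())
    return citing


def filter_citing_articles(citing: set[str], corpus: CitationCorpus, seeds: SeedSet) -> set[str]:
    """Drop excluded articles and those published after the cutoff year.

    Articles with unknown year are retained (with a warning): an export
    without a year is more often incomplete metadata than a future paper.
    """
    kept: set[str] = set()
    for article_id in citing:
        if article_id in seeds.exclusion_ids:
            continue
        year = corpus.articles[article_id].year if article_id in corpus.articles else None
        if seeds.date_cutoff_year is not None:
            if year is None:
                logger.warning("citing article %s has unknown year; retained", article_id)
            elif year > seeds.date_cutoff_year:
                continue
        kept.add(article_id)
    return kept


def count_cocitations(
    corpus: CitationCorpus, citing: set[str], seeds: SeedSet
) -> CoCitationTable:
    """Count, per candidate work, the distinct citing articles listing it.

    ``citing`` must already be filtered.  Seed keys and the unusable
    sentinel are dropped from the records; the j-index is computed against
    ``n_citing = len(citing)``.  An empty citing set yields an empty table
    with ``n_citing = 0`` (a valid result signalling an uncited seed).
    """
    skeys = seed_refkeys(corpus, seeds)
    counter: Counter[RefKey] = Counter()
    for article_id in citing:
        for key in set(corpus.articles[article_id].cited_refs):
            counter[key] += 1
    n_citing = len(citing)
    records = [
        CoCitationRecord(refkey=key, cocitation_count=count, j_index=100.0 * count / n_citing, rank=0)
        for key, count in counter.items()
        if key not in skeys and key != UNUSABLE_KEY
    ]
    records.sort(key=lambda r: (-r.cocitation_count, r.refkey))
    for i, rec in enumerate(records, start=1):
        rec.rank = i
    return CoCitationTable(records=records, n_citing=n_citing, seed_keys=skeys)


def run_cocitation_search(corpus: CitationCorpus, seeds: SeedSet) -> CoCitationTable:
    """Collect citing articles, filter them, count co-citations; record provenance."""
    collected = collect_citing_articles(corpus, seeds)
    filtered = filter_citing_articles(collected, corpus, seeds)
    table = count_cocitations(corpus, filtered, seeds)
    table.provenance = {
        "known_ids": sorted(seeds.known_ids),
        "exclusion_ids": sorted(seeds.exclusion_ids),
        "date_cutoff_year": seeds.date_cutoff_year,
        "n_citing_collected": len(collected),
        "n_citing": len(filtered),
        "seed_keys": sorted(table.seed_keys),
    }
    return table
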