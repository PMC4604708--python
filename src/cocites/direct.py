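"""Second-stage expansion over direct citations.

Co-citation ranking cannot reach works that nobody has cited alongside the
seeds — most importantly articles too recent to have been cited at all.
The second search therefore looks at *direct* links: starting from a query
set (the seeds plus everything retrieved in the first stage), it gathers
every work that any query member cites (backward) and every corpus article
that cites any query member (forward), counts per candidate the distinct
query members it is linked to in either direction, and keeps candidates
with at least two links.

A pair linked both ways (X cites S and S cites X cannot happen for a
single pair, but X may cite S1 while S2 cites X) contributes one link per
distinct query member, never two for the same member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Optional

from .engine import CoCitationTable, SeedSet, run_cocitation_search, seed_refkeys
from .io import CitationCorpus, RefKey, UNUSABLE_KEY
from .selection import SelectionResult, select_composite

logger = logging.getLogger("cocites")


@dataclass
class DirectCitationRecord:
    """One candidate with its direct-link tally against the query set.

    ``as_cited`` counts query members that cite the candidate;
    ``as_citer`` counts query members the candidate cites; ``n_links``
    counts distinct linked members (a member linked both ways counts once),
    so ``as_cited + as_citer >= n_links``.
    """

    refkey: RefKey
    n_links: int
    as_cited: int
    as_citer: int


def expand_direct(
    corpus: CitationCorpus,
    query_set: set[RefKey],
    date_cutoff_year: Optional[int] = None,
) -> list[DirectCitationRecord]:
    """Rank non-query works by distinct direct links to the query set.

    Query members without an indexed article contribute no backward list
    (their references are unknown); they still attract forward links.
    When ``date_cutoff_year`` is set it is applied uniformly: indexed
    candidates published after the cutoff are dropped, and citing articles
    published after the cutoff generate no links.
    """
    if not query_set:
        raise ValueError("direct expansion needs a non-empty query set")

    linked_members: dict[RefKey, set[RefKey]] = {}
    cited_by_members: dict[RefKey, set[RefKey]] = {}
    citing_members: dict[RefKey, set[RefKey]] = {}

    def _too_recent(article_id: str) -> bool:
        if date_cutoff_year is None:
            return False
        year = corpus.articles[article_id].year
        return year is not None and year > date_cutoff_year

    unindexed = sorted(k for k in query_set if k not in corpus.article_of_refkey)
    if unindexed:
        logger.info(
            "%d query members have no indexed article; backward lists unavailable for %s",
            len(unindexed), unindexed[:5],
        )

    for member in query_set:
        # backward: works on the member's own reference list
        article_id = corpus.article_of_refkey.get(member)
        if article_id is not None and not _too_recent(article_id):
            for candidate in set(corpus.articles[article_id].cited_refs):
                linked_members.setdefault(candidate, set()).add(member)
                cited_by_members.setdefault(candidate, set()).add(member)
        # forward: corpus articles citing the member
        for citer_id in corpus.cited_by.get(member, set()):
            if _too_recent(citer_id):
                continue
            candidate = corpus.refkey_of_article[citer_id]
            linked_members.setdefault(candidate, set()).add(member)
            citing_members.setdefault(candidate, set()).add(member)

    records = []
    for candidate, members in linked_members.items():
        if candidate in query_set or candidate == UNUSABLE_KEY:
            continue
        article_id = corpus.article_of_refkey.get(candidate)
        if article_id is not None and _too_recent(article_id):
            continue
        records.append(
            DirectCitationRecord(
                refkey=candidate,
                n_links=len(members),
                as_cited=len(cited_by_members.get(candidate, set())),
                as_citer=len(citing_members.get(candidate, set())),
            )
        )
    records.sort(key=lambda r: (-r.n_links, r.refkey))
    return records


def select_direct(records: list[DirectCitationRecord], min_links: int = 2) -> SelectionResult:
    """Keep candidates with at least ``min_links`` direct links (default 2)."""
    if min_links < 1:
        raise ValueError("min_links must be >= 1")
    keys = [r.refkey for r in records if r.n_links >= min_links]
    return SelectionResult(
        strategy="direct_min_links", threshold_used=min_links, selected_keys=keys, size=len(keys)
    )


@dataclass
class TwoStageResult:
    """Outcome of the full two-search protocol with per-stage provenance."""

    stage1_table: CoCitationTable
    stage1_selection: SelectionResult
    direct_records: list[DirectCitationRecord]
    stage2_selection: SelectionResult
    combined: SelectionResult
    provenance: dict[str, Any] = field(default_factory=dict)


def run_two_stage_search(
    corpus: CitationCorpus,
    seeds: SeedSet,
    min_links: int = 2,
    apply_cutoff_to_direct: bool = True,
) -> TwoStageResult:
    """Composite-threshold co-citation search followed by direct expansion.

    Stage 1 ranks co-citations and applies the composite (count > 1 and
    j-index > 1 %) rule.  Stage 2 expands direct citations around the
    seeds plus the stage-1 selection and keeps candidates with
    ``min_links`` or more links.  The combined screening set is the union,
    with stage-1 candidates listed first and never re-screened.
    """
    table = run_cocitation_search(corpus, seeds)
    stage1 = select_composite(table)

    query = seed_refkeys(corpus, seeds) | stage1.key_set
    cutoff = seeds.date_cutoff_year if apply_cutoff_to_direct else None
    direct_records = expand_direct(corpus, query, date_cutoff_year=cutoff)
    stage2 = select_direct(direct_records, min_links=min_links)

    stage1_keys = set(stage1.selected_keys)
    combined_keys = list(stage1.selected_keys) + [
        k for k in stage2.selected_keys if k not in stage1_keys
    ]
    combined = SelectionResult(
        strategy="two_stage",
        threshold_used=None,
        selected_keys=combined_keys,
        size=len(combined_keys),
    )
    provenance = {
        "stage1": {"strategy": stage1.strategy, "size": stage1.size, **table.provenance},
        "stage2": {
            "min_links": min_links,
            "query_size": len(query),
            "size": stage2.size,
            "date_cutoff_year": cutoff,
            "overlap_with_stage1": len(stage1_keys & stage2.key_set),
        },
    }
    return TwoStageResult(
        stage1_table=table,
        stage1_selection=stage1,
        direct_records=direct_records,
        stage2_selection=stage2,
        combined=combined,
        provenance=provenance,
    )
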