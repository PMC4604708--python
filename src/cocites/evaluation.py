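"""Evaluation against a gold standard, plus direct-citation network analysis.

A search is judged on two axes:

* **accuracy** — the percentage of the gold-standard included studies that
  appear in the screened selection, and
* **efficiency** — the size of the screened selection as a percentage of
  the number of articles the original (keyword-based) search screened.

Percentages are rounded to the nearest integer, halves away from zero;
medians over a collection of evaluations take the mean of the two middle
values on even lengths and round the same way.  Missed gold studies are
classified by the first matching reason in a fixed precedence order
(abstract-only, non-English, pre-1975, too recent, other) — the strata a
citation-based search is structurally prone to missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .io import CitationCorpus, RefKey

logger = logging.getLogger("cocites")

MISSED_CATEGORIES = ("abstract", "non_english", "old_pre1975", "recent", "other")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (not banker's rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percentage(numerator: int, denominator: int) -> int:
    """Rounded integer percentage."""
    if denominator <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_away(100.0 * numerator / denominator)


def median_rounded(values: Sequence[float]) -> int:
    """Median; even lengths average the two middle values, then round half-away."""
    if not values:
        raise ValueError("median of empty sequence")
    ordered = sorted(values)
    n = len(ordered)
    if n % 2 == 1:
        return round_half_away(float(ordered[n // 2]))
    return round_half_away((ordered[n // 2 - 1] + ordered[n // 2]) / 2.0)


# ---------------------------------------------------------------------------
# Direct-citation network of a study set
# ---------------------------------------------------------------------------


@dataclass
class StudyNetwork:
    """Undirected direct-citation network over a set of included studies."""

    nodes: set[RefKey]
    edges: set[frozenset]
    components: list[set[RefKey]]
    n_disconnected: int


def build_study_network(corpus: CitationCorpus, studies: set[RefKey]) -> StudyNetwork:
    """Link two studies when either one's indexed article cites the other.

    Studies without an indexed article have no reference list and become
    isolated nodes unless another study cites them by key.
    """
    if not studies:
        raise ValueError("study network needs at least one study")
    graph = nx.Graph()
    graph.add_nodes_from(studies)
    unindexed = 0
    for study in studies:
        article_id = corpus.article_of_refkey.get(study)
        if article_id is None:
            unindexed += 1
            continue
        for cited in corpus.articles[article_id].cited_refs:
            if cited in studies and cited != study:
                graph.add_edge(study, cited)
    if unindexed:
        logger.info("%d of %d studies have no indexed article", unindexed, len(studies))
    components = [set(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), min(c)))
    n_disconnected = sum(1 for c in components if len(c) == 1)
    return StudyNetwork(
        nodes=set(studies),
        edges={frozenset(e) for e in graph.edges()},
        components=components,
        n_disconnected=n_disconnected,
    )


# ---------------------------------------------------------------------------
# Evaluation reports
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Accuracy/efficiency of one selection against one gold standard."""

    n_screened: int
    n_screened_original: int
    screening_pct: int
    n_included: int
    n_retrieved: int
    retrieval_pct: int
    missed: list[tuple[RefKey, str]] = field(default_factory=list)
    label: str = ""


def report_from_counts(
    n_screened: int,
    n_screened_original: int,
    n_included: int,
    n_retrieved: int,
    label: str = "",
) -> EvaluationReport:
    """Build a report from bare counts (no study identities available)."""
    if n_included < 1:
        raise ValueError("gold standard must contain at least one study")
    if n_screened_original < 1:
        raise ValueError("original screening count must be >= 1")
    return EvaluationReport(
        n_screened=n_screened,
        n_screened_original=n_screened_original,
        screening_pct=percentage(n_screened, n_screened_original),
        n_included=n_included,
        n_retrieved=n_retrieved,
        retrieval_pct=percentage(n_retrieved, n_included),
        label=label,
    )


def evaluate_search(
    selected: set[RefKey],
    gold_included: set[RefKey],
    n_screened_original: int,
    corpus: Optional[CitationCorpus] = None,
    search_year: Optional[int] = None,
    label: str = "",
) -> EvaluationReport:
    """Compare a screened selection with the gold-standard included studies.

    Retrieval is the share of gold studies present in the selection;
    screening is the selection size relative to the original search's
    screening count.  When a corpus and search year are given, missed
    studies are classified with :func:`classify_missed`; otherwise they
    fall in the ``other`` category (gold studies indexed nowhere are
    missed the same way as any other).
    """
    if not gold_included:
        raise ValueError("gold standard must contain at least one study")
    missed_keys = sorted(gold_included - set(selected))
    if corpus is not None and search_year is not None:
        missed = classify_missed(missed_keys, corpus, search_year)
    else:
        missed = [(k, "other") for k in missed_keys]
    report = report_from_counts(
        n_screened=len(selected),
        n_screened_original=n_screened_original,
        n_included=len(gold_included),
        n_retrieved=len(gold_included & set(selected)),
        label=label,
    )
    report.missed = missed
    return report


def classify_missed(
    missed_keys: Iterable[RefKey],
    corpus: CitationCorpus,
    search_year: int,
) -> list[tuple[RefKey, str]]:
    """Assign each missed study its first matching category.

    Precedence: abstract-only > non-English > pre-1975 > published in or
    after the search year > other.  Studies without an indexed article
    have no metadata and fall to ``other``.
    """
    out: list[tuple[RefKey, str]] = []
    for key in missed_keys:
        article_id = corpus.article_of_refkey.get(key)
        if article_id is None:
            out.append((key, "other"))
            continue
        a = corpus.articles[article_id]
        if a.doc_type == "abstract":
            category = "abstract"
        elif a.language and a.language.strip().lower() not in ("english", "en"):
            category = "non_english"
        elif a.year is not None and a.year < 1975:
            category = "old_pre1975"
        elif a.year is not None and a.year >= search_year:
            category = "recent"
        else:
            category = "other"
        out.append((key, category))
    return out


@dataclass
class AggregateSummary:
    """Column-wise medians over a collection of evaluation reports."""

    n_reports: int
    median_screened: int
    median_screened_original: int
    median_included: int
    median_retrieved: int
    median_screening_pct: int
    median_retrieval_pct: int


def aggregate_reports(reports: Sequence[EvaluationReport]) -> AggregateSummary:
    """Column-wise medians over evaluation reports.

    Percentage medians are taken over the exact (unrounded) per-report
    ratios and rounded once at the end; rounding each report first and
    then taking the median can shift the summary by a point when the two
    middle reports straddle a half.
    """
    if not reports:
        raise ValueError("nothing to aggregate")
    return AggregateSummary(
        n_reports=len(reports),
        median_screened=median_rounded([r.n_screened for r in reports]),
        median_screened_original=median_rounded([r.n_screened_original for r in reports]),
        median_included=median_rounded([r.n_included for r in reports]),
        median_retrieved=median_rounded([r.n_retrieved for r in reports]),
        median_screening_pct=median_rounded(
            [100.0 * r.n_screened / r.n_screened_original for r in reports]
        ),
        median_retrieval_pct=median_rounded(
            [100.0 * r.n_retrieved / r.n_included for r in reports]
        ),
    )
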