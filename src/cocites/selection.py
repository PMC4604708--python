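"""Threshold strategies for choosing which ranked candidates to screen.

Three rules are implemented, trading retrieval against screening burden:

* a plain minimum co-citation count (``k = 1`` screens everything,
  ``k = 2`` is the usual low threshold),
* the "frequently co-cited" window rule — pick the integer threshold whose
  stratum-cumulative selection size falls in [100, 150], or failing that
  the size closest to 100, and
* the composite rule — co-cited more than once *and* in more than 1 % of
  the citing articles (the j-index), which tightens automatically on
  densely cited topics: below 100 citing articles the count condition
  binds, above it the percentage condition does.

Because records with equal counts are selected or rejected together,
every selection is a rank-prefix of the table (strata are never split).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .engine import CoCitationTable
from .io import RefKey


@dataclass
class SelectionResult:
    """The screened subset produced by one threshold strategy."""

    strategy: str
    threshold_used: Optional[Union[int, float]]
    selected_keys: list[RefKey]
    size: int

    @property
    def key_set(self) -> set[RefKey]:
        return set(self.selected_keys)


def _result(strategy: str, threshold: Optional[Union[int, float]], keys: list[RefKey]) -> SelectionResult:
    return SelectionResult(strategy=strategy, threshold_used=threshold, selected_keys=keys, size=len(keys))


def compute_j_index(count: int, n_citing: int) -> float:
    """Co-citation count as an (unrounded) percentage of the citing articles."""
    if n_citing < 1:
        raise ValueError("j-index undefined for zero citing articles")
    if not 1 <= count <= n_citing:
        raise ValueError(f"count {count} outside [1, {n_citing}]")
    return 100.0 * count / n_citing


def select_min_count(table: CoCitationTable, k: int) -> SelectionResult:
    """All candidates co-cited at least ``k`` times, in rank order."""
    if k < 1:
        raise ValueError("minimum co-citation count must be >= 1")
    keys = [r.refkey for r in table.records if r.cocitation_count >= k]
    strategy = "all" if k == 1 else ("min_count_2" if k == 2 else "min_count")
    return _result(strategy, k, keys)


def select_frequent(
    table: CoCitationTable, target_low: int = 100, target_high: int = 150
) -> SelectionResult:
    """The "frequently co-cited" stratum: aim for a screening set of 100–150.

    Every integer threshold from 1 to the maximum count is evaluated; the
    selection size at a threshold is stratum-cumulative (all candidates at
    or above it).  The largest threshold whose size lands in the window is
    chosen (the smallest in-window screening set); if no threshold lands in
    the window, the one whose size is closest to ``target_low`` wins, ties
    going to the smaller set.
    """
    if not table.records:
        raise ValueError("cannot choose a frequent-co-citation threshold on an empty table")
    max_count = table.records[0].cocitation_count
    sizes = {t: table.size_at_threshold(t) for t in range(1, max_count + 1)}
    in_window = [t for t, size in sizes.items() if target_low <= size <= target_high]
    if in_window:
        chosen = max(in_window)
    else:
        # closest to target_low; ties to the larger threshold (smaller set)
        chosen = min(sizes, key=lambda t: (abs(sizes[t] - target_low), -t))
    keys = [r.refkey for r in table.records if r.cocitation_count >= chosen]
    return _result("frequent", chosen, keys)


def select_composite(table: CoCitationTable) -> SelectionResult:
    """Co-cited more than once and in more than 1 % of citing articles.

    Both conditions are strict as written (count >= 2, j-index > 1.0).
    For fewer than 100 citing articles this reduces exactly to the
    minimum-count-2 rule, since any count >= 2 then exceeds 1 %.
    """
    keys = [
        r.refkey
        for r in table.records
        if r.cocitation_count >= 2 and r.j_index > 1.0
    ]
    return _result("composite", 1.0, keys)
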