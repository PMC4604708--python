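"""Published benchmark counts for the co-citation search method.

Two published validation studies re-ran the search against the included
studies of published meta-analyses: a pilot on 10 meta-analyses comparing
three selection thresholds (screen everything co-cited, everything
co-cited at least twice, and the "frequently co-cited" 100–150 window),
and a larger study on 42 meta-analyses using the composite count/j-index
threshold followed by a direct-citation second search.

This module ships the per-meta-analysis counts those studies reported —
articles screened by the original keyword search, studies included, and
articles screened / studies retrieved per strategy — together with the
percentage cells as printed, so the evaluation and aggregation code can
be checked against them cell by cell.  The counts are inputs, not
results: every percentage and median in this package is recomputed from
the raw counts at run time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .evaluation import AggregateSummary, EvaluationReport, aggregate_reports, report_from_counts

STUDY1_STRATEGIES = ("all", "min2", "frequent")
STUDY2_STAGES = ("stage1", "combined")


@dataclass(frozen=True)
class Study1Row:
    """One pilot-study meta-analysis: counts plus the printed percentages."""

    label: str
    screened_original: int
    included: int
    #: per strategy: (screened, retrieved, printed screening %, printed retrieval %)
    all: tuple[int, int, int, int]
    min2: tuple[int, int, int, int]
    frequent: tuple[int, int, int, int]


STUDY1_ROWS: tuple[Study1Row, ...] = (
    Study1Row("Boothe", 17500, 8, (5595, 8, 32, 100), (913, 8, 5, 100), (109, 8, 1, 100)),
    Study1Row("Frolkis", 9151, 12, (967, 10, 11, 83), (224, 7, 2, 58), (108, 6, 1, 50)),
    Study1Row("Oliver-Williams", 8646, 10, (588, 8, 7, 80), (62, 5, 1, 50), (62, 5, 1, 50)),
    Study1Row("Knoll", 2365, 21, (7638, 19, 323, 90), (1719, 18, 73, 86), (132, 11, 6, 52)),
    Study1Row("Stevanovic", 2090, 13, (987, 12, 47, 92), (186, 10, 9, 77), (77, 10, 4, 77)),
    Study1Row("DeVries", 1194, 9, (8388, 9, 703, 100), (1924, 9, 161, 100), (124, 8, 10, 89)),
    Study1Row("Crider", 1154, 5, (1006, 5, 87, 100), (120, 5, 10, 100), (120, 5, 10, 100)),
    Study1Row("Herretes", 898, 4, (670, 3, 75, 75), (111, 3, 12, 75), (111, 3, 12, 75)),
    Study1Row("Gharaibeh", 836, 27, (880, 26, 105, 96), (173, 21, 21, 78), (116, 19, 14, 70)),
    Study1Row("Gu", 784, 6, (3234, 6, 413, 100), (780, 6, 99, 100), (129, 5, 16, 83)),
)

#: Printed median row of the pilot study, per strategy:
#: (median screened, median retrieved, median screening %, median retrieval %)
STUDY1_PRINTED_MEDIANS = {
    "screened_original": 1642,
    "included": 10,
    "all": (997, 9, 81, 94),
    "min2": (205, 8, 11, 82),
    "frequent": (110, 7, 8, 76),
}

#: Per-meta-analysis counts of included studies with no direct-citation link
#: to any other included study, and how many of them each threshold retrieved:
#: (label, n_without_direct_links, retrieved_all, retrieved_min2, retrieved_frequent)
STUDY1_DISCONNECTED: tuple[tuple[str, int, int, int, int], ...] = (
    ("Boothe", 1, 1, 1, 1),
    ("Frolkis", 8, 7, 5, 4),
    ("Oliver-Williams", 5, 3, 0, 0),
    ("Knoll", 16, 14, 14, 7),
    ("Stevanovic", 4, 4, 2, 2),
    ("DeVries", 4, 4, 4, 2),
    ("Crider", 1, 1, 1, 1),
    ("Herretes", 0, 0, 0, 0),
    ("Gharaibeh", 14, 13, 8, 6),
    ("Gu", 2, 2, 2, 1),
)


@dataclass(frozen=True)
class Study2Row:
    """One meta-analysis of the larger study: counts plus printed percentages."""

    label: str
    screened_original: int
    included: int
    n_citing: int
    #: per stage: (screened, retrieved, printed screening %, printed retrieval %)
    stage1: tuple[int, int, int, int]
    combined: tuple[int, int, int, int]


STUDY2_ROWS: tuple[Study2Row, ...] = (
    Study2Row("Mehrabi", 4148, 29, 170, (1113, 29, 27, 100), (1383, 29, 33, 100)),
    Study2Row("Pathak", 543, 6, 1437, (584, 6, 108, 100), (886, 6, 163, 100)),
    Study2Row("Viswanathan", 2749, 6, 74, (627, 6, 23, 100), (689, 6, 25, 100)),
    Study2Row("Vrablik", 7771, 3, 28, (68, 3, 1, 100), (81, 3, 1, 100)),
    Study2Row("vanWely", 894, 18, 106, (444, 18, 50, 100), (615, 18, 69, 100)),
    Study2Row("Schuit", 39, 13, 171, (1221, 12, 3131, 92), (1385, 13, 3551, 100)),
    Study2Row("Deng", 362, 9, 928, (533, 8, 147, 89), (1726, 9, 477, 100)),
    Study2Row("Nwachuku", 464, 15, 62, (404, 13, 87, 87), (502, 15, 108, 100)),
    Study2Row("Gu-2011", 764, 19, 104, (719, 16, 94, 84), (908, 19, 119, 100)),
    Study2Row("SanLorenzo", 3529, 19, 67, (296, 15, 8, 79), (468, 19, 13, 100)),
    Study2Row("Al-Wassia", 166, 7, 8, (32, 4, 19, 57), (52, 7, 31, 100)),
    Study2Row("Elshaer", 750, 30, 35, (210, 21, 28, 70), (235, 29, 31, 97)),
    Study2Row("Mumme", 701, 21, 55, (271, 19, 39, 90), (468, 20, 67, 95)),
    Study2Row("Hazlewood", 1463, 35, 897, (861, 28, 59, 80), (3162, 33, 216, 94)),
    Study2Row("Sheyin", 221, 17, 40, (180, 16, 81, 94), (392, 16, 177, 94)),
    Study2Row("Yuan", 7175, 14, 51, (490, 10, 7, 71), (596, 13, 8, 93)),
    Study2Row("Elmariah", 1934, 14, 3870, (599, 5, 31, 36), (836, 13, 43, 93)),
    Study2Row("Cheelo", 1192, 11, 112, (919, 9, 77, 82), (1017, 10, 85, 91)),
    Study2Row("Gu-2015", 326, 18, 14, (59, 13, 18, 72), (233, 16, 71, 89)),
    Study2Row("Saleh", 1480, 14, 49, (964, 12, 65, 86), (1055, 12, 71, 86)),
    Study2Row("Emdin", 10598, 45, 3223, (395, 26, 4, 58), (6116, 36, 58, 80)),
    Study2Row("Sayegh", 594, 22, 69, (529, 14, 89, 64), (759, 17, 128, 77)),
    Study2Row("Kamper", 6189, 41, 968, (857, 28, 14, 68), (1227, 31, 20, 76)),
    Study2Row("Taioli", 98, 24, 85, (441, 16, 450, 67), (595, 18, 607, 75)),
    Study2Row("Sharpe", 3875, 7, 92, (886, 5, 23, 71), (911, 5, 24, 71)),
    Study2Row("Zhang", 468, 7, 221, (140, 5, 30, 71), (198, 5, 42, 71)),
    Study2Row("Siddiqui", 3119, 13, 129, (824, 8, 26, 62), (1002, 9, 32, 69)),
    Study2Row("Mair-Jenkins", 1449, 32, 75, (971, 22, 67, 69), (1086, 22, 75, 69)),
    Study2Row("Bonitsis", 795, 52, 117, (937, 30, 118, 58), (1489, 34, 187, 65)),
    Study2Row("Williams", 1976, 19, 21, (95, 10, 5, 53), (186, 12, 9, 63)),
    Study2Row("Souto", 4527, 23, 580, (913, 12, 20, 52), (1372, 14, 30, 61)),
    Study2Row("Zhen", 742, 25, 59, (215, 13, 29, 52), (290, 15, 39, 60)),
    Study2Row("Shan", 243, 19, 60, (289, 9, 119, 47), (344, 11, 142, 58)),
    Study2Row("Marcuzzi", 5009, 15, 85, (739, 7, 15, 47), (851, 8, 17, 53)),
    Study2Row("Lipinski", 824, 17, 420, (531, 6, 64, 35), (610, 9, 74, 53)),
    Study2Row("Stevens", 400, 6, 62, (536, 3, 134, 50), (551, 3, 138, 50)),
    Study2Row("Bernstein", 1837, 53, 98, (376, 19, 20, 36), (505, 22, 27, 42)),
    Study2Row("Avni", 5365, 103, 104, (698, 29, 13, 28), (1259, 39, 23, 38)),
    Study2Row("Kumar", 573, 16, 101, (926, 5, 162, 31), (1013, 5, 177, 31)),
    Study2Row("Fazeli", 1195, 5, 4, (7, 1, 1, 20), (7, 1, 1, 20)),
    Study2Row("Brydges", 11628, 33, 63, (347, 4, 3, 12), (391, 6, 3, 18)),
    Study2Row("McNally", 2453, 88, 45, (374, 6, 15, 7), (399, 9, 16, 10)),
)

#: Printed median row of the larger study, per stage:
#: (median screened, median retrieved, median screening %, median retrieval %)
STUDY2_PRINTED_MEDIANS = {
    "screened_original": 1194,
    "included": 18,
    "n_citing": 85,
    "stage1": (530, 12, 29, 69),
    "combined": (652, 13, 50, 79),
}


def study1_reports(strategy: str) -> list[EvaluationReport]:
    """Evaluation reports for the pilot study under one selection strategy."""
    if strategy not in STUDY1_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STUDY1_STRATEGIES}")
    reports = []
    for row in STUDY1_ROWS:
        screened, retrieved, _, _ = getattr(row, strategy)
        reports.append(
            report_from_counts(
                n_screened=screened,
                n_screened_original=row.screened_original,
                n_included=row.included,
                n_retrieved=retrieved,
                label=row.label,
            )
        )
    return reports


def study2_reports(stage: str) -> list[EvaluationReport]:
    """Evaluation reports for the larger study at one stage of the protocol."""
    if stage not in STUDY2_STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STUDY2_STAGES}")
    reports = []
    for row in STUDY2_ROWS:
        screened, retrieved, _, _ = getattr(row, stage)
        reports.append(
            report_from_counts(
                n_screened=screened,
                n_screened_original=row.screened_original,
                n_included=row.included,
                n_retrieved=retrieved,
                label=row.label,
            )
        )
    return reports


def study1_summary(strategy: str) -> AggregateSummary:
    return aggregate_reports(study1_reports(strategy))


def study2_summary(stage: str) -> AggregateSummary:
    return aggregate_reports(study2_reports(stage))


def study1_totals(strategy: str) -> tuple[int, int]:
    """(total studies retrieved, total studies in scope) for one strategy.

    Thresholds nest, so the universe at a stricter threshold is what the
    looser one retrieved: 115 included overall, of which the full
    co-citation list finds 106, the twice-co-cited list 92 and the
    frequently-co-cited list 80.
    """
    retrieved = sum(getattr(row, strategy)[1] for row in STUDY1_ROWS)
    if strategy == "all":
        universe = sum(row.included for row in STUDY1_ROWS)
    elif strategy == "min2":
        universe = sum(row.all[1] for row in STUDY1_ROWS)
    else:
        universe = sum(row.min2[1] for row in STUDY1_ROWS)
    return retrieved, universe


def disconnected_totals(strategy: str = "all") -> tuple[int, int]:
    """(retrieved, total) for included studies with no direct links."""
    column = {"all": 2, "min2": 3, "frequent": 4}[strategy]
    total = sum(r[1] for r in STUDY1_DISCONNECTED)
    retrieved = sum(r[column] for r in STUDY1_DISCONNECTED)
    return retrieved, total
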