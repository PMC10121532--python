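"""Published aggregate counts of the source evaluation study, plus
deterministic expansion into exam-level fixture cohorts.

The study this package re-implements analysed a cancer-enriched sample from
a Norwegian population-based screening programme (2010-2018): 949
screen-detected cancers, 305 interval cancers and 12,642 age- and
year-matched negative examinations, all scored by a commercial AI system
(raw score 0.0-10.0, binned 1-10).  Its exam-level data are not public, but
its aggregate tables are printed in full; this module carries those counts
and reconstructs minimal exam-level cohorts whose re-tabulation reproduces
them exactly, so every evaluation operation can be exercised against the
published numbers.

All dictionaries hold per-AI-bin counts as 10-element lists (bins 1..10)
unless noted otherwise.
"""

from __future__ import annotations

from itertools import cycle, islice
from typing import Sequence

from .core_records import (
    HistoType,
    OutcomeClass,
    ReaderOutcomeTable,
    ScoreOutcomeTable,
    ScreeningExam,
    TumorCharacteristics,
    expand_fixture,
)

__all__ = [
    "SCORE_OUTCOME_COUNTS",
    "READER_OUTCOME_COUNTS",
    "PRIOR_EXAM_COUNTS",
    "HISTOTYPE_COUNTS",
    "INVASIVE_PATHOLOGY",
    "VDG4_COUNTS",
    "VDG_COUNTS",
    "VDG_DISTRIBUTION",
    "score_outcome_table",
    "reader_outcome_table",
    "study_exams",
    "study_prior_exams",
    "vdg4_exams",
]

# Exam counts per AI bin x outcome class (column totals 12,642 / 949 / 305).
SCORE_OUTCOME_COUNTS: dict[str, list[int]] = {
    "negative": [3023, 1060, 1158, 1096, 1049, 939, 936, 1073, 1155, 1153],
    "screen_detected": [3, 2, 1, 3, 6, 4, 7, 15, 28, 880],
    "interval": [23, 10, 14, 14, 13, 17, 18, 19, 55, 122],
}

# Reader-workflow counts per AI bin (totals 1526 / 958 / 215 / 734 / 9 / 33 / 8).
READER_OUTCOME_COUNTS: dict[str, list[int]] = {
    "n_consensus": [71, 26, 36, 51, 51, 49, 56, 61, 114, 1011],
    "n_recalled": [3, 2, 1, 4, 6, 4, 7, 15, 29, 887],
    "n_sdc_pos_one": [1, 1, 0, 1, 2, 1, 1, 3, 11, 194],
    "n_sdc_pos_both": [2, 1, 1, 2, 4, 3, 6, 12, 17, 686],
    "n_recalled_negative": [0, 0, 0, 1, 0, 0, 0, 0, 1, 7],
    "n_ic_pos_one": [0, 0, 1, 2, 0, 2, 2, 0, 9, 17],
    "n_ic_pos_both": [0, 1, 0, 0, 0, 0, 0, 0, 1, 6],
}

# Prior screening round for the 745 screen-detected cancers with a prior
# exam: counts per prior-exam AI bin (totals 745 / 131 / 41 / 94 / 37).
PRIOR_EXAM_COUNTS: dict[str, list[int]] = {
    "n": [55, 26, 32, 28, 39, 37, 51, 48, 117, 312],
    "n_consensus": [0, 2, 3, 1, 3, 5, 4, 6, 21, 86],
    "n_recalled": [0, 1, 1, 0, 0, 1, 2, 4, 8, 24],
    "n_pos_one": [0, 1, 2, 1, 3, 5, 4, 2, 14, 62],
    "n_pos_both": [0, 1, 1, 0, 0, 0, 0, 4, 7, 24],
}

# Histotype counts per outcome class x AI score group (10 vs below 10),
# in the order (dcis, invasive NST, invasive lobular, other invasive).
HISTOTYPE_COUNTS: dict[tuple[str, str], dict[HistoType, int]] = {
    ("screen_detected", "10"): {
        HistoType.DCIS: 184,
        HistoType.INVASIVE_NST: 608,
        HistoType.INVASIVE_LOBULAR: 57,
        HistoType.OTHER_INVASIVE: 31,
    },
    ("screen_detected", "<10"): {
        HistoType.DCIS: 11,
        HistoType.INVASIVE_NST: 49,
        HistoType.INVASIVE_LOBULAR: 5,
        HistoType.OTHER_INVASIVE: 4,
    },
    ("interval", "10"): {
        HistoType.DCIS: 4,
        HistoType.INVASIVE_NST: 99,
        HistoType.INVASIVE_LOBULAR: 14,
        HistoType.OTHER_INVASIVE: 5,
    },
    ("interval", "<10"): {
        HistoType.DCIS: 6,
        HistoType.INVASIVE_NST: 137,
        HistoType.INVASIVE_LOBULAR: 34,
        HistoType.OTHER_INVASIVE: 6,
    },
}

# Pathology of invasive tumours per outcome class x AI score group:
# diameter median and IQR (mm) with its missing count, grade counts 1/2/3
# with missing, binary nodal status (positive count, missing), and NPI
# summaries (mean, SD, category counts excellent/good/moderate/poor,
# missing).
INVASIVE_PATHOLOGY: dict[tuple[str, str], dict] = {
    ("screen_detected", "10"): {
        "n": 696,
        "diameter": {"median": 14.0, "q1": 10.0, "q3": 21.0, "missing": 10},
        "grade": {"counts": (201, 288, 199), "missing": 8},
        "nodes": {"positive": 148, "missing": 8},
        "npi": {"mean": 3.6, "sd": 1.1, "categories": (161, 205, 271, 42), "missing": 17},
    },
    ("screen_detected", "<10"): {
        "n": 58,
        "diameter": {"median": 11.0, "q1": 8.0, "q3": 15.0, "missing": 2},
        "grade": {"counts": (15, 24, 16), "missing": 3},
        "nodes": {"positive": 10, "missing": 2},
        "npi": {"mean": 3.5, "sd": 1.0, "categories": (12, 20, 20, 2), "missing": 4},
    },
    ("interval", "10"): {
        "n": 118,
        "diameter": {"median": 22.0, "q1": 13.0, "q3": 28.0, "missing": 10},
        "grade": {"counts": (22, 43, 42), "missing": 11},
        "nodes": {"positive": 47, "missing": 0},
        "npi": {"mean": 4.0, "sd": 1.2, "categories": (16, 19, 51, 18), "missing": 14},
    },
    ("interval", "<10"): {
        "n": 177,
        "diameter": {"median": 23.0, "q1": 15.0, "q3": 31.0, "missing": 17},
        "grade": {"counts": (21, 67, 77), "missing": 12},
        "nodes": {"positive": 71, "missing": 0},
        "npi": {"mean": 4.2, "sd": 1.0, "categories": (10, 27, 97, 24), "missing": 19},
    },
}

# Highest density grade (VDG 4): cancer counts and their AI-score-10 subsets.
VDG4_COUNTS = {"n_sdc": 59, "n_sdc_bin10": 59, "n_ic": 35, "n_ic_bin10": 17}

# Exams per VDG grade 1..4 among those with a density measurement (the
# published rounded shares 15/49/30/7% sum to 101%, so the raw counts are
# kept and normalised where a probability vector is needed).
VDG_COUNTS = (1916, 6111, 3782, 891)

# Marginal VDG shares in the study sample (grades 1..4), normalised.
VDG_DISTRIBUTION = tuple(c / sum(VDG_COUNTS) for c in VDG_COUNTS)


def score_outcome_table() -> ScoreOutcomeTable:
    """The published exam-count grid as a :class:`ScoreOutcomeTable`."""
    return ScoreOutcomeTable.from_columns(**SCORE_OUTCOME_COUNTS)


def reader_outcome_table() -> ReaderOutcomeTable:
    """The published reader-workflow grid as a :class:`ReaderOutcomeTable`."""
    return ReaderOutcomeTable.from_columns(**READER_OUTCOME_COUNTS)


def _assign_tumors(cancers: Sequence[ScreeningExam], group: tuple[str, str]) -> None:
    """Assign histopathology to one cancer group, deterministically in order.

    Histotypes, grades and nodal status are dealt out to match the group's
    published counts exactly.  Diameters of the non-missing invasive tumours
    cycle through (q1, median, q3): under linear-interpolation quantiles the
    resulting multiset reproduces the published median and IQR exactly.
    Nodal status is recorded as the binary flag only (no counts are
    published), so NPI values are deliberately left uncomputable here.
    """
    histo_plan: list[HistoType] = []
    for histo, count in HISTOTYPE_COUNTS[group].items():
        histo_plan.extend([histo] * count)
    if len(histo_plan) != len(cancers):
        raise ValueError(
            f"group {group}: {len(cancers)} exams but {len(histo_plan)} histotype slots"
        )
    for exam, histo in zip(cancers, histo_plan):
        exam.tumor = TumorCharacteristics(histo_type=histo)

    invasive = [e.tumor for e in cancers if e.tumor.histo_type.is_invasive]
    path = INVASIVE_PATHOLOGY[group]
    assert len(invasive) == path["n"]

    d = path["diameter"]
    n_with_diameter = path["n"] - d["missing"]
    diam_values = list(islice(cycle((d["q1"], d["median"], d["q3"])), n_with_diameter))
    for t, value in zip(invasive, diam_values):
        t.diameter_mm = value

    g1, g2, g3 = path["grade"]["counts"]
    grade_plan = [1] * g1 + [2] * g2 + [3] * g3
    for t, grade in zip(invasive, grade_plan):
        t.grade = grade

    n_node_known = path["n"] - path["nodes"]["missing"]
    node_plan = [True] * path["nodes"]["positive"] + [False] * (
        n_node_known - path["nodes"]["positive"]
    )
    for t, flag in zip(invasive, node_plan):
        t.node_positive = flag


def study_exams() -> list[ScreeningExam]:
    """Exam-level reconstruction of the full published study sample.

    13,896 exams whose tabulations reproduce the published exam-count and
    reader-workflow grids exactly, with cancer histopathology dealt out to
    match the published tumour tables, and prior-exam links attached for
    the 745 screen-detected cancers analysed at the preceding round (see
    :func:`study_prior_exams`).
    """
    exams = expand_fixture(score_outcome_table(), reader_outcome_table(), id_prefix="study")
    for outcome in ("screen_detected", "interval"):
        for score_group, keep in (("10", lambda b: b == 10), ("<10", lambda b: b < 10)):
            members = [
                e
                for e in exams
                if e.outcome_class.value == outcome and keep(e.ai_bin)
            ]
            _assign_tumors(members, (outcome, score_group))
    sdc = [e for e in exams if e.outcome_class is OutcomeClass.SCREEN_DETECTED]
    n_with_prior = sum(PRIOR_EXAM_COUNTS["n"])
    for k, exam in enumerate(sdc[:n_with_prior]):
        exam.prior_exam_id = f"prior-{k + 1:04d}"
    return exams


def study_prior_exams() -> list[ScreeningExam]:
    """Prior-round exams matching the links set by :func:`study_exams`.

    One negative-outcome exam per linked screen-detected cancer, with AI
    bin, consensus, recall and reader-positivity dealt out per the published
    prior-round grid: within each bin, both-positive exams first, then
    one-positive, with recalls drawn from the consensus exams.
    """
    priors: list[ScreeningExam] = []
    serial = 0
    for b in range(1, 11):
        i = b - 1
        n = PRIOR_EXAM_COUNTS["n"][i]
        n_both = PRIOR_EXAM_COUNTS["n_pos_both"][i]
        n_one = PRIOR_EXAM_COUNTS["n_pos_one"][i]
        n_recalled = PRIOR_EXAM_COUNTS["n_recalled"][i]
        assert PRIOR_EXAM_COUNTS["n_consensus"][i] == n_both + n_one <= n
        assert n_recalled <= n_both + n_one
        scores = [(2, 2)] * n_both + [(2, 1)] * n_one + [(1, 1)] * (n - n_both - n_one)
        for j, (r1, r2) in enumerate(scores):
            serial += 1
            priors.append(
                ScreeningExam(
                    exam_id=f"prior-{serial:04d}",
                    woman_id=f"prior-w-{serial:04d}",
                    age_years=56,
                    screen_year=2012,
                    outcome_class=OutcomeClass.NEGATIVE,
                    reader1_score=r1,
                    reader2_score=r2,
                    consensus_flag=r1 >= 2 or r2 >= 2,
                    recall_flag=j < n_recalled,
                    ai_raw=b - 0.5,
                    ai_bin=b,
                )
            )
    return priors


def vdg4_exams() -> list[ScreeningExam]:
    """Cancers of the highest-density stratum (VDG 4) as exam records.

    59 screen-detected cancers, all with AI score 10, and 35 interval
    cancers of which 17 scored 10; the below-10 interval cancers sit at bin
    5 (their published distribution across bins 1-9 is not available, and
    no stratum-level rate depends on which sub-10 bin they occupy).
    """
    exams: list[ScreeningExam] = []

    def add(outcome: OutcomeClass, bin_: int, recall: bool, n: int, tag: str) -> None:
        for k in range(n):
            exams.append(
                ScreeningExam(
                    exam_id=f"vdg4-{tag}-{k + 1:03d}",
                    woman_id=f"vdg4-w-{tag}-{k + 1:03d}",
                    age_years=58,
                    screen_year=2014,
                    outcome_class=outcome,
                    reader1_score=2 if recall else 1,
                    reader2_score=2 if recall else 1,
                    consensus_flag=recall,
                    recall_flag=recall,
                    ai_raw=bin_ - 0.5,
                    ai_bin=bin_,
                    vdg=4,
                    tumor=TumorCharacteristics(histo_type=HistoType.INVASIVE_NST),
                )
            )

    add(OutcomeClass.SCREEN_DETECTED, 10, True, VDG4_COUNTS["n_sdc_bin10"], "sdc10")
    add(OutcomeClass.INTERVAL, 10, False, VDG4_COUNTS["n_ic_bin10"], "ic10")
    add(
        OutcomeClass.INTERVAL,
        5,
        False,
        VDG4_COUNTS["n_ic"] - VDG4_COUNTS["n_ic_bin10"],
        "iclo",
    )
    return exams
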