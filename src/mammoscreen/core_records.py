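"""Exam-level data model, cohort file I/O, and aggregate-table conversion.

The unit of analysis is one screening examination (:class:`ScreeningExam`):
its outcome class (negative / screen-detected cancer / interval cancer), the
two radiologists' interpretation scores (1-5) with the consensus and recall
flags they imply, the AI malignancy score (continuous raw value in
[0.0, 10.0] plus its ten-level bin), automated volumetric density (VDG 1-4),
histopathology for cancers, and an optional link to the woman's previous
screening examination.

Published results in this setting are aggregate tables stratified by AI
score bin.  Two table shapes are modelled — exam counts per bin x outcome
class (:class:`ScoreOutcomeTable`) and reader-behaviour counts per bin
(:class:`ReaderOutcomeTable`) — together with :func:`tabulate_scores` /
:func:`tabulate_reader_outcomes` to aggregate exam records, and
:func:`expand_fixture` to reconstruct minimal exam-level records from
printed aggregates so that every downstream operation can run on them.
"""

from __future__ import annotations


from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .clinical_scores import NpiCategory, bin_ai_score, categorize_npi, compute_npi

__all__ = [
    "OutcomeClass",
    "HistoType",
    "TumorCharacteristics",
    "ScreeningExam",
    "ScoreOutcomeTable",
    "ReaderOutcomeTable",
    "CohortFormatError",
    "CohortValidationError",
    "AggregateConsistencyError",
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "tabulate_scores",
    "tabulate_reader_outcomes",
    "expand_fixture",
]


class OutcomeClass(str, Enum):
    """Final screening outcome of an examination."""

    NEGATIVE = "negative"
    SCREEN_DETECTED = "screen_detected"
    INTERVAL = "interval"


class HistoType(str, Enum):
    """Histologic cancer type."""

    DCIS = "dcis"
    INVASIVE_NST = "invasive_nst"
    INVASIVE_LOBULAR = "invasive_lobular"
    OTHER_INVASIVE = "other_invasive"

    @property
    def is_invasive(self) -> bool:
        return self is not HistoType.DCIS


@dataclass
class TumorCharacteristics:
    """Histopathology of a detected cancer.

    ``node_positive`` is the binary nodal status used in summary tables;
    when a positive-node count is available the flag is derived from it,
    and only the count (never the bare flag) feeds the NPI, which needs
    the nodal stage.  The NPI is defined for invasive tumours only.
    """

    histo_type: HistoType
    diameter_mm: Optional[float] = None
    grade: Optional[int] = None
    n_positive_nodes: Optional[int] = None
    node_positive: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.node_positive is None and self.n_positive_nodes is not None:
            self.node_positive = self.n_positive_nodes > 0

    @property
    def npi(self) -> Optional[float]:
        if not self.histo_type.is_invasive:
            return None
        return compute_npi(self.diameter_mm, self.grade, self.n_positive_nodes)

    @property
    def npi_category(self) -> Optional[NpiCategory]:
        return categorize_npi(self.npi)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        errors: list[str] = []
        if self.diameter_mm is not None and self.diameter_mm <= 0:
            errors.append(f"diameter_mm must be positive, got {self.diameter_mm}")
        if self.grade is not None and self.grade not in (1, 2, 3):
            errors.append(f"grade must be 1-3, got {self.grade}")
        if self.n_positive_nodes is not None and self.n_positive_nodes < 0:
            errors.append(f"n_positive_nodes must be >= 0, got {self.n_positive_nodes}")
        if (
            self.n_positive_nodes is not None
            and self.node_positive is not None
            and self.node_positive != (self.n_positive_nodes > 0)
        ):
            errors.append(
                "node_positive contradicts n_positive_nodes "
                f"({self.node_positive} vs {self.n_positive_nodes} nodes)"
            )
        return errors


@dataclass
class ScreeningExam:
    """One screening episode for one woman."""

    exam_id: str
    woman_id: str
    age_years: int
    screen_year: int
    outcome_class: OutcomeClass
    reader1_score: int
    reader2_score: int
    consensus_flag: bool
    recall_flag: bool
    ai_raw: float
    ai_bin: int
    vdg: Optional[int] = None
    tumor: Optional[TumorCharacteristics] = None
    prior_exam_id: Optional[str] = None

    @property
    def is_cancer(self) -> bool:
        return self.outcome_class is not OutcomeClass.NEGATIVE

    def reader_score(self, reader: str) -> int:
        if reader == "reader1":
            return self.reader1_score
        if reader == "reader2":
            return self.reader2_score
        raise ValueError(f"reader must be 'reader1' or 'reader2', got {reader!r}")

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid).

        The invariants encode the screening workflow: any exam scored >= 2
        by either reader goes to consensus; recall can only follow a
        consensus discussion; a screen-detected cancer is by definition
        recalled and has histopathology; an interval cancer has
        histopathology but surfaced after the screen.
        """
        e: list[str] = []
        for name, score in (("reader1_score", self.reader1_score), ("reader2_score", self.reader2_score)):
            if score not in (1, 2, 3, 4, 5):
                e.append(f"{name} must be 1-5, got {score}")
        if not 0.0 <= self.ai_raw <= 10.0:
            e.append(f"ai_raw must lie in [0.0, 10.0], got {self.ai_raw}")
        else:
            if self.ai_bin != bin_ai_score(self.ai_raw):
                e.append(
                    f"ai_bin={self.ai_bin} inconsistent with ai_raw={self.ai_raw} "
                    f"(expected {bin_ai_score(self.ai_raw)})"
                )
        expected_consensus = self.reader1_score >= 2 or self.reader2_score >= 2
        if self.consensus_flag != expected_consensus:
            e.append(
                "consensus_flag must equal (reader1_score >= 2 or reader2_score >= 2); "
                f"got consensus_flag={self.consensus_flag} with scores "
                f"({self.reader1_score}, {self.reader2_score})"
            )
        if self.recall_flag and not self.consensus_flag:
            e.append("recall_flag requires consensus_flag")
        if self.outcome_class is OutcomeClass.SCREEN_DETECTED:
            if not self.recall_flag:
                e.append("screen-detected cancer requires recall_flag")
            if self.tumor is None:
                e.append("screen-detected cancer requires tumor characteristics")
        if self.outcome_class is OutcomeClass.INTERVAL and self.tumor is None:
            e.append("interval cancer requires tumor characteristics")
        if self.vdg is not None and self.vdg not in (1, 2, 3, 4):
            e.append(f"vdg must be 1-4 or missing, got {self.vdg}")
        if self.tumor is not None:
            e.extend(f"tumor: {msg}" for msg in self.tumor.validate())
        return e


# ---------------------------------------------------------------------------
# Aggregate table shapes
# ---------------------------------------------------------------------------

AI_BINS = tuple(range(1, 11))
_OUTCOME_COLS = [c.value for c in OutcomeClass]

READER_TABLE_COLUMNS = [
    "n_consensus",
    "n_recalled",
    "n_sdc_pos_one",
    "n_sdc_pos_both",
    "n_recalled_negative",
    "n_ic_pos_one",
    "n_ic_pos_both",
]


class AggregateConsistencyError(ValueError):
    """Raised when printed aggregate counts contradict each other."""


@dataclass
class ScoreOutcomeTable:
    """10 x 3 grid of exam counts: AI score bin x outcome class.

    ``counts`` is indexed by AI bin 1..10 with columns
    ``negative, screen_detected, interval``.
    """

    counts: pd.DataFrame

    @classmethod
    def from_columns(
        cls,
        negative: Sequence[int],
        screen_detected: Sequence[int],
        interval: Sequence[int],
    ) -> "ScoreOutcomeTable":
        df = pd.DataFrame(
            {
                "negative": list(negative),
                "screen_detected": list(screen_detected),
                "interval": list(interval),
            },
            index=pd.Index(AI_BINS, name="ai_bin"),
            dtype="int64",
        )
        return cls(df)

    def __post_init__(self) -> None:
        df = self.counts
        if list(df.index) != list(AI_BINS) or list(df.columns) != _OUTCOME_COLS:
            raise AggregateConsistencyError(
                "counts must be indexed by ai_bin 1..10 with columns "
                f"{_OUTCOME_COLS}; got index={list(df.index)} columns={list(df.columns)}"
            )
        if (df.to_numpy() < 0).any():
            raise AggregateConsistencyError("counts must be non-negative")

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def all_cancers(self) -> pd.Series:
        """Per-bin counts of screen-detected plus interval cancers."""
        return self.counts["screen_detected"] + self.counts["interval"]

    def percentages(self) -> pd.DataFrame:
        """Within-column percentages, rounded to one decimal for display."""
        totals = self.column_totals
        pct = self.counts.div(totals.where(totals > 0), axis=1) * 100.0
        return pct.round(1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreOutcomeTable):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass
class ReaderOutcomeTable:
    """Per AI bin, reader-workflow counts.

    Columns: exams discussed at consensus; exams recalled; screen-detected
    cancers flagged (score >= 2) by exactly one / by both readers; recalled
    exams with a negative outcome; interval cancers flagged by exactly one /
    by both readers at the index screen.
    """

    counts: pd.DataFrame

    @classmethod
    def from_columns(cls, **columns: Sequence[int]) -> "ReaderOutcomeTable":
        df = pd.DataFrame(
            {name: list(columns[name]) for name in READER_TABLE_COLUMNS},
            index=pd.Index(AI_BINS, name="ai_bin"),
            dtype="int64",
        )
        return cls(df)

    def __post_init__(self) -> None:
        df = self.counts
        if list(df.index) != list(AI_BINS) or list(df.columns) != READER_TABLE_COLUMNS:
            raise AggregateConsistencyError(
                f"counts must be indexed by ai_bin 1..10 with columns {READER_TABLE_COLUMNS}"
            )
        if (df.to_numpy() < 0).any():
            raise AggregateConsistencyError("counts must be non-negative")
        if (df["n_recalled"] > df["n_consensus"]).any():
            raise AggregateConsistencyError("recalls exceed consensus in some bin")

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReaderOutcomeTable):
            return NotImplemented
        return self.counts.equals(other.counts)


# ---------------------------------------------------------------------------
# Cohort file I/O
# ---------------------------------------------------------------------------

#: Column contract for cohort CSV files (UTF-8, header required, booleans as
#: 0/1, missing values as empty strings).  ``node_positive`` carries binary
#: nodal status for records where no positive-node count is available.
COHORT_COLUMNS = [
    "exam_id",
    "woman_id",
    "age_years",
    "screen_year",
    "outcome_class",
    "reader1_score",
    "reader2_score",
    "consensus",
    "recall",
    "ai_raw",
    "ai_bin",
    "vdg",
    "histo_type",
    "diameter_mm",
    "grade",
    "n_positive_nodes",
    "node_positive",
    "prior_exam_id",
]


class CohortFormatError(ValueError):
    """Raised when a cohort file does not match the column contract."""


class CohortValidationError(ValueError):
    """Raised when cohort rows violate record invariants.

    ``violations`` maps 1-based data-row numbers to lists of messages.
    """

    def __init__(self, violations: dict[int, list[str]]):
        self.violations = violations
        lines = [
            f"  row {row}: {msg}" for row, msgs in sorted(violations.items()) for msg in msgs
        ]
        super().__init__(
            f"{len(violations)} cohort row(s) violate record invariants:\n" + "\n".join(lines)
        )


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, Enum):
        return str(value.value)
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _exam_to_row(exam: ScreeningExam) -> list[str]:
    t = exam.tumor
    return [
        _fmt(exam.exam_id),
        _fmt(exam.woman_id),
        _fmt(exam.age_years),
        _fmt(exam.screen_year),
        _fmt(exam.outcome_class),
        _fmt(exam.reader1_score),
        _fmt(exam.reader2_score),
        _fmt(exam.consensus_flag),
        _fmt(exam.recall_flag),
        _fmt(exam.ai_raw),
        _fmt(exam.ai_bin),
        _fmt(exam.vdg),
        _fmt(t.histo_type if t else None),
        _fmt(t.diameter_mm if t else None),
        _fmt(t.grade if t else None),
        _fmt(t.n_positive_nodes if t else None),
        _fmt(t.node_positive if t else None),
        _fmt(exam.prior_exam_id),
    ]


def write_cohort(exams: Iterable[ScreeningExam], path: Union[str, Path]) -> None:
    """Write exam records to a cohort CSV with deterministic column order.

    The encoding is stable: writing, re-reading and writing again produces a
    byte-identical file.
    """
    rows = [_exam_to_row(e) for e in exams]
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS, dtype="object")
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def _parse_opt_int(raw: str, column: str, row: int, errors: dict[int, list[str]]) -> Optional[int]:
    if raw == "":
        return None
    try:
        return int(raw)
    except ValueError:
        errors.setdefault(row, []).append(f"{column}: not an integer: {raw!r}")
        return None


def _parse_opt_float(raw: str, column: str, row: int, errors: dict[int, list[str]]) -> Optional[float]:
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        errors.setdefault(row, []).append(f"{column}: not a number: {raw!r}")
        return None


def read_cohort(path: Union[str, Path]) -> list[ScreeningExam]:
    """Read and validate a cohort CSV.

    Every row becomes a :class:`ScreeningExam`; all invariant violations are
    collected and reported together with their 1-based data-row numbers in a
    single :class:`CohortValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "node_positive"]
    if missing:
        raise CohortFormatError(f"cohort file {path} lacks mandatory column(s): {missing}")
    has_node_flag = "node_positive" in df.columns

    exams: list[ScreeningExam] = []
    errors: dict[int, list[str]] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        row = rec._asdict()
        try:
            outcome = OutcomeClass(row["outcome_class"])
        except ValueError:
            errors.setdefault(i, []).append(f"outcome_class: unknown value {row['outcome_class']!r}")
            continue
        histo_raw = row["histo_type"]
        tumor: Optional[TumorCharacteristics] = None
        if histo_raw != "":
            try:
                histo = HistoType(histo_raw)
            except ValueError:
                errors.setdefault(i, []).append(f"histo_type: unknown value {histo_raw!r}")
                continue
            node_flag_raw = row["node_positive"] if has_node_flag else ""
            tumor = TumorCharacteristics(
                histo_type=histo,
                diameter_mm=_parse_opt_float(row["diameter_mm"], "diameter_mm", i, errors),
                grade=_parse_opt_int(row["grade"], "grade", i, errors),
                n_positive_nodes=_parse_opt_int(row["n_positive_nodes"], "n_positive_nodes", i, errors),
                node_positive=None if node_flag_raw == "" else node_flag_raw == "1",
            )
        ai_raw = _parse_opt_float(row["ai_raw"], "ai_raw", i, errors)
        if ai_raw is None:
            errors.setdefault(i, []).append("ai_raw: mandatory value missing")
            continue
        exam = ScreeningExam(
            exam_id=row["exam_id"],
            woman_id=row["woman_id"],
            age_years=_parse_opt_int(row["age_years"], "age_years", i, errors) or 0,
            screen_year=_parse_opt_int(row["screen_year"], "screen_year", i, errors) or 0,
            outcome_class=outcome,
            reader1_score=_parse_opt_int(row["reader1_score"], "reader1_score", i, errors) or 0,
            reader2_score=_parse_opt_int(row["reader2_score"], "reader2_score", i, errors) or 0,
            consensus_flag=row["consensus"] == "1",
            recall_flag=row["recall"] == "1",
            ai_raw=ai_raw,
            ai_bin=_parse_opt_int(row["ai_bin"], "ai_bin", i, errors) or 0,
            vdg=_parse_opt_int(row["vdg"], "vdg", i, errors),
            prior_exam_id=row["prior_exam_id"] or None,
        )
        exam.tumor = tumor
        violations = exam.validate()
        if violations:
            errors.setdefault(i, []).extend(violations)
        exams.append(exam)
    if errors:
        raise CohortValidationError(errors)
    return exams


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def tabulate_scores(exams: Iterable[ScreeningExam]) -> ScoreOutcomeTable:
    """Count exams per AI score bin x outcome class (the score-outcome grid)."""
    counts = pd.DataFrame(0, index=pd.Index(AI_BINS, name="ai_bin"), columns=_OUTCOME_COLS, dtype="int64")
    for exam in exams:
        counts.loc[exam.ai_bin, exam.outcome_class.value] += 1
    return ScoreOutcomeTable(counts)


def _n_positive_readers(exam: ScreeningExam) -> int:
    return int(exam.reader1_score >= 2) + int(exam.reader2_score >= 2)


def tabulate_reader_outcomes(exams: Iterable[ScreeningExam]) -> ReaderOutcomeTable:
    """Count reader-workflow outcomes per AI score bin.

    Per bin: exams discussed at consensus, exams recalled, screen-detected
    cancers with a positive interpretation (score >= 2) by exactly one / by
    both readers, recalled exams with a negative outcome, and interval
    cancers with one / both readers positive at the index screen.
    """
    counts = pd.DataFrame(
        0, index=pd.Index(AI_BINS, name="ai_bin"), columns=READER_TABLE_COLUMNS, dtype="int64"
    )
    for exam in exams:
        b = exam.ai_bin
        npos = _n_positive_readers(exam)
        if exam.consensus_flag:
            counts.loc[b, "n_consensus"] += 1
        if exam.recall_flag:
            counts.loc[b, "n_recalled"] += 1
        if exam.outcome_class is OutcomeClass.SCREEN_DETECTED:
            if npos == 1:
                counts.loc[b, "n_sdc_pos_one"] += 1
            elif npos == 2:
                counts.loc[b, "n_sdc_pos_both"] += 1
        elif exam.outcome_class is OutcomeClass.INTERVAL:
            if npos == 1:
                counts.loc[b, "n_ic_pos_one"] += 1
            elif npos == 2:
                counts.loc[b, "n_ic_pos_both"] += 1
        elif exam.recall_flag:
            counts.loc[b, "n_recalled_negative"] += 1
    return ReaderOutcomeTable(counts)


# ---------------------------------------------------------------------------
# Fixture expansion: printed aggregates -> minimal exam-level records
# ---------------------------------------------------------------------------


def _default_tumor() -> TumorCharacteristics:
    return TumorCharacteristics(histo_type=HistoType.INVASIVE_NST)


def expand_fixture(
    score_table: Optional[ScoreOutcomeTable] = None,
    reader_table: Optional[ReaderOutcomeTable] = None,
    *,
    vdg: Optional[int] = None,
    age_years: int = 58,
    screen_year: int = 2014,
    id_prefix: str = "fx",
) -> list[ScreeningExam]:
    """Reconstruct minimal exam-level records from printed aggregate tables.

    Re-tabulating the result reproduces the input aggregates exactly.  Raw AI
    scores are set to the bin midpoint (bin - 0.5); unspecified fields take
    documented defaults (age 58, a mid-study screening year, a no-detail
    invasive tumour record for cancers).  Reader-score splits are assigned
    deterministically in bin order: "one positive reader" records score
    (2, 1), "both positive" (2, 2), others (1, 1).

    With only a score table, screen-detected cancers are recalled with both
    readers positive and all other exams are reader-negative.  With a reader
    table (alone or joint), per-bin splits follow its columns; the recalled
    column must equal screen-detected plus recalled-negative counts, the
    convention under which interval cancers are not recalled at the index
    screen.  Contradictory aggregates raise
    :class:`AggregateConsistencyError`.
    """
    if score_table is None and reader_table is None:
        raise ValueError("at least one of score_table and reader_table is required")

    if score_table is None:
        assert reader_table is not None
        rt = reader_table.counts
        score_table = ScoreOutcomeTable.from_columns(
            negative=rt["n_consensus"]
            - rt["n_sdc_pos_one"]
            - rt["n_sdc_pos_both"]
            - rt["n_ic_pos_one"]
            - rt["n_ic_pos_both"],
            screen_detected=rt["n_sdc_pos_one"] + rt["n_sdc_pos_both"],
            interval=rt["n_ic_pos_one"] + rt["n_ic_pos_both"],
        )

    st = score_table.counts
    if reader_table is not None:
        rt = reader_table.counts
        bad = rt["n_sdc_pos_one"] + rt["n_sdc_pos_both"] != st["screen_detected"]
        if bad.any():
            raise AggregateConsistencyError(
                "screen-detected reader splits do not sum to the screen-detected "
                f"count in bin(s) {list(st.index[bad])}"
            )
        bad = rt["n_ic_pos_one"] + rt["n_ic_pos_both"] > st["interval"]
        if bad.any():
            raise AggregateConsistencyError(
                f"interval-cancer reader positives exceed interval count in bin(s) {list(st.index[bad])}"
            )
        bad = rt["n_recalled"] != st["screen_detected"] + rt["n_recalled_negative"]
        if bad.any():
            raise AggregateConsistencyError(
                "recalled column must equal screen-detected plus recalled-negative "
                f"counts; violated in bin(s) {list(st.index[bad])}"
            )
        consensus_negatives = (
            rt["n_consensus"]
            - st["screen_detected"]
            - rt["n_ic_pos_one"]
            - rt["n_ic_pos_both"]
            - rt["n_recalled_negative"]
        )
        if (consensus_negatives < 0).any():
            raise AggregateConsistencyError(
                "consensus column smaller than its cancer and recalled-negative parts"
            )
        bad = rt["n_recalled_negative"] + consensus_negatives > st["negative"]
        if bad.any():
            raise AggregateConsistencyError(
                f"consensus negatives exceed negative count in bin(s) {list(st.index[bad])}"
            )

    exams: list[ScreeningExam] = []
    serial = 0

    def add(
        bin_: int,
        outcome: OutcomeClass,
        r1: int,
        r2: int,
        recall: bool,
        n: int,
    ) -> None:
        nonlocal serial
        consensus = r1 >= 2 or r2 >= 2
        for _ in range(int(n)):
            serial += 1
            exams.append(
                ScreeningExam(
                    exam_id=f"{id_prefix}-{serial:06d}",
                    woman_id=f"{id_prefix}-w-{serial:06d}",
                    age_years=age_years,
                    screen_year=screen_year,
                    outcome_class=outcome,
                    reader1_score=r1,
                    reader2_score=r2,
                    consensus_flag=consensus,
                    recall_flag=recall,
                    ai_raw=bin_ - 0.5,
                    ai_bin=bin_,
                    vdg=vdg,
                    tumor=_default_tumor() if outcome is not OutcomeClass.NEGATIVE else None,
                )
            )

    for b in AI_BINS:
        n_sdc = int(st.loc[b, "screen_detected"])
        n_ic = int(st.loc[b, "interval"])
        n_neg = int(st.loc[b, "negative"])
        if reader_table is None:
            add(b, OutcomeClass.SCREEN_DETECTED, 2, 2, True, n_sdc)
            add(b, OutcomeClass.INTERVAL, 1, 1, False, n_ic)
            add(b, OutcomeClass.NEGATIVE, 1, 1, False, n_neg)
        else:
            rt = reader_table.counts
            sdc_one = int(rt.loc[b, "n_sdc_pos_one"])
            add(b, OutcomeClass.SCREEN_DETECTED, 2, 1, True, sdc_one)
            add(b, OutcomeClass.SCREEN_DETECTED, 2, 2, True, n_sdc - sdc_one)
            ic_one = int(rt.loc[b, "n_ic_pos_one"])
            ic_both = int(rt.loc[b, "n_ic_pos_both"])
            add(b, OutcomeClass.INTERVAL, 2, 1, False, ic_one)
            add(b, OutcomeClass.INTERVAL, 2, 2, False, ic_both)
            add(b, OutcomeClass.INTERVAL, 1, 1, False, n_ic - ic_one - ic_both)
            rec_neg = int(rt.loc[b, "n_recalled_negative"])
            cons_neg = int(
                rt.loc[b, "n_consensus"] - n_sdc - ic_one - ic_both - rec_neg
            )
            add(b, OutcomeClass.NEGATIVE, 2, 1, True, rec_neg)
            add(b, OutcomeClass.NEGATIVE, 2, 1, False, cons_neg)
            add(b, OutcomeClass.NEGATIVE, 1, 1, False, n_neg - rec_neg - cons_neg)
    return exams
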