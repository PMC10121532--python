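"""Evaluation of the AI malignancy score against independent double reading.

Operations on exam-level cohorts:

* confusion accounting for a single reader and for the double-reading
  programme as a whole;
* calibration of the continuous AI raw-score threshold to match a target
  specificity (the operating point at which AI and first-reader
  sensitivities are compared);
* sensitivity of the "AI score 10" rule, overall and stratified by
  volumetric breast density;
* histopathological tumour summaries by outcome class and AI score group;
* analysis of the AI score on the screening round before cancer detection;
* a pre-screen-reading triage simulation (exclude low-scoring exams from
  the human reading stream).

Because the cohorts this package targets are cancer-enriched (each cancer
matched to several negative exams), sensitivity and specificity computed
here are comparison tools between readers and AI on the same sample, not
population estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_records import (
    AI_BINS,
    HistoType,
    OutcomeClass,
    ScreeningExam,
)

__all__ = [
    "Rate",
    "ConfusionCounts",
    "ThresholdResult",
    "StratumSensitivity",
    "StratifiedSensitivityReport",
    "GroupTumorSummary",
    "TumorSummary",
    "PriorExamReport",
    "TriageReport",
    "reader_confusion",
    "double_reading_confusion",
    "matched_specificity_threshold",
    "ai_score10_sensitivity",
    "stratified_sensitivity",
    "tumor_summary",
    "prior_exam_analysis",
    "triage_simulate",
    "one_reader_only_consensus_share",
]


@dataclass(frozen=True)
class Rate:
    """A proportion carried as numerator/denominator.

    ``value`` is ``None`` when the denominator is zero (an undefined rate is
    reported as missing, never as zero).
    """

    numerator: int
    denominator: int

    @property
    def value(self) -> Optional[float]:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    @property
    def pct(self) -> Optional[float]:
        v = self.value
        return None if v is None else 100.0 * v


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts over cancers and negative-outcome exams."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sensitivity(self) -> Optional[float]:
        return Rate(self.tp, self.tp + self.fn).value

    @property
    def specificity(self) -> Optional[float]:
        return Rate(self.tn, self.tn + self.fp).value


def reader_confusion(exams: Iterable[ScreeningExam], reader: str) -> ConfusionCounts:
    """Single-reader confusion counts.

    A reader call is positive when that reader's interpretation score is
    >= 2, i.e. the exam would be forwarded to consensus on that reader's
    account.  Cancers (screen-detected and interval alike) with a positive
    call are true positives — including cancers that were recalled with a
    negative assessment before surfacing as interval cancers — and cancers
    missed by the reader are false negatives.  Negative-outcome exams with a
    positive call are false positives.
    """
    tp = fn = fp = tn = 0
    for exam in exams:
        positive = exam.reader_score(reader) >= 2
        if exam.is_cancer:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def double_reading_confusion(exams: Iterable[ScreeningExam]) -> ConfusionCounts:
    """Programme-level confusion counts for independent double reading.

    Detection means actual detection at the screen: screen-detected cancers
    are true positives and interval cancers are misses, even those discussed
    at consensus or recalled with a negative assessment.  False positives
    are negative-outcome exams that were recalled.
    """
    tp = fn = fp = tn = 0
    for exam in exams:
        if exam.outcome_class is OutcomeClass.SCREEN_DETECTED:
            tp += 1
        elif exam.outcome_class is OutcomeClass.INTERVAL:
            fn += 1
        elif exam.recall_flag:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of matching the AI raw-score threshold to a target specificity."""

    threshold: float
    achieved_specificity: float
    sensitivity_at_threshold: Optional[float]
    target_specificity: float
    n_negative: int
    n_cancer: int


def matched_specificity_threshold(
    exams: Sequence[ScreeningExam], target_specificity: float
) -> ThresholdResult:
    """Calibrate the continuous AI raw-score cut to a target specificity.

    An exam is AI-positive when ``ai_raw > threshold``.  On a finite sample
    the attainable specificities form a step function whose candidate cuts
    are the distinct raw scores of the negative-outcome exams; the cut whose
    specificity is closest to the target is returned, ties broken toward the
    higher specificity (the higher cut).  Typical use sets the target to the
    observed first-reader specificity so that AI and reader sensitivities
    are compared at the same operating point.
    """
    if not 0.0 <= target_specificity <= 1.0:
        raise ValueError(f"target specificity must lie in [0, 1], got {target_specificity}")
    neg = np.array([e.ai_raw for e in exams if not e.is_cancer], dtype=float)
    if neg.size == 0:
        raise ValueError("at least one negative-outcome exam is required")
    cancer = np.array([e.ai_raw for e in exams if e.is_cancer], dtype=float)

    candidates = np.unique(neg)  # sorted ascending
    # specificity at cut t: share of negatives with raw <= t
    spec = np.searchsorted(np.sort(neg), candidates, side="right") / neg.size
    gap = np.abs(spec - target_specificity)
    best = np.flatnonzero(gap == gap.min())[-1]  # last index = higher cut on ties
    threshold = float(candidates[best])
    sens = Rate(int((cancer > threshold).sum()), cancer.size).value if cancer.size else None
    return ThresholdResult(
        threshold=threshold,
        achieved_specificity=float(spec[best]),
        sensitivity_at_threshold=sens,
        target_specificity=target_specificity,
        n_negative=int(neg.size),
        n_cancer=int(cancer.size),
    )


def ai_score10_sensitivity(
    exams: Iterable[ScreeningExam], vdg: Optional[int] = None
) -> Rate:
    """Sensitivity of the "AI score 10" rule: cancers in bin 10 over all cancers.

    With ``vdg`` given, both numerator and denominator are restricted to
    exams of that density grade.
    """
    num = den = 0
    for exam in exams:
        if not exam.is_cancer:
            continue
        if vdg is not None and exam.vdg != vdg:
            continue
        den += 1
        num += exam.ai_bin == 10
    return Rate(num, den)


@dataclass(frozen=True)
class StratumSensitivity:
    """Sensitivities within one density stratum, with their count bases."""

    stratum: str
    n_sdc: int
    n_ic: int
    first_reader: Rate
    double_reading: Rate
    ai_score10: Rate


@dataclass
class StratifiedSensitivityReport:
    """First-reader, double-reading and AI-score-10 sensitivity per VDG stratum."""

    strata: dict[str, StratumSensitivity] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata.values():
            rows.append(
                {
                    "stratum": s.stratum,
                    "n_sdc": s.n_sdc,
                    "n_ic": s.n_ic,
                    "first_reader_pct": s.first_reader.pct,
                    "double_reading_pct": s.double_reading.pct,
                    "ai_score10_pct": s.ai_score10.pct,
                }
            )
        return pd.DataFrame(rows)


def _stratum_sensitivity(label: str, exams: Sequence[ScreeningExam]) -> StratumSensitivity:
    cancers = [e for e in exams if e.is_cancer]
    n_sdc = sum(e.outcome_class is OutcomeClass.SCREEN_DETECTED for e in cancers)
    rc = reader_confusion(exams, "reader1")
    dr = double_reading_confusion(exams)
    return StratumSensitivity(
        stratum=label,
        n_sdc=n_sdc,
        n_ic=len(cancers) - n_sdc,
        first_reader=Rate(rc.tp, rc.tp + rc.fn),
        double_reading=Rate(dr.tp, dr.tp + dr.fn),
        ai_score10=ai_score10_sensitivity(exams),
    )


def stratified_sensitivity(exams: Sequence[ScreeningExam]) -> StratifiedSensitivityReport:
    """Sensitivities per Volpara Density Grade stratum, plus unknown and overall.

    Strata with no cancers report missing rates, never zero.
    """
    report = StratifiedSensitivityReport()
    for grade in (1, 2, 3, 4):
        subset = [e for e in exams if e.vdg == grade]
        report.strata[f"vdg{grade}"] = _stratum_sensitivity(f"vdg{grade}", subset)
    unknown = [e for e in exams if e.vdg is None]
    if unknown:
        report.strata["unknown"] = _stratum_sensitivity("unknown", unknown)
    report.strata["overall"] = _stratum_sensitivity("overall", list(exams))
    return report


# ---------------------------------------------------------------------------
# Tumour characteristic summaries
# ---------------------------------------------------------------------------


@dataclass
class GroupTumorSummary:
    """Histopathology summary for one outcome-class x AI-score group.

    Percentages use non-missing denominators; missing counts are reported
    separately.  Size, grade and nodal fields cover invasive tumours only;
    NPI statistics cover the cases where the index is computable.
    """

    outcome_class: OutcomeClass
    score_group: str  # "10" or "<10"
    n: int
    histotype_counts: dict[str, int]
    n_invasive: int
    diameter_median: Optional[float]
    diameter_q1: Optional[float]
    diameter_q3: Optional[float]
    diameter_missing: int
    grade_counts: dict[int, int]
    grade_missing: int
    node_positive: Rate
    node_missing: int
    npi_mean: Optional[float]
    npi_sd: Optional[float]
    npi_category_counts: dict[str, int]
    npi_missing: int

    @property
    def histotype_pct(self) -> dict[str, Optional[float]]:
        return {k: Rate(v, self.n).pct for k, v in self.histotype_counts.items()}

    @property
    def grade_pct(self) -> dict[int, Optional[float]]:
        known = sum(self.grade_counts.values())
        return {k: Rate(v, known).pct for k, v in self.grade_counts.items()}

    @property
    def npi_category_pct(self) -> dict[str, Optional[float]]:
        known = sum(self.npi_category_counts.values())
        return {k: Rate(v, known).pct for k, v in self.npi_category_counts.items()}


@dataclass
class TumorSummary:
    """Tumour summaries for the four outcome-class x AI-score groups."""

    groups: dict[tuple[str, str], GroupTumorSummary]

    def group(self, outcome: OutcomeClass, score_group: str) -> GroupTumorSummary:
        return self.groups[(outcome.value, score_group)]


def _summarize_group(
    outcome: OutcomeClass, score_group: str, exams: Sequence[ScreeningExam]
) -> GroupTumorSummary:
    tumors = [e.tumor for e in exams if e.tumor is not None]
    histo_counts = {h.value: 0 for h in HistoType}
    for t in tumors:
        histo_counts[t.histo_type.value] += 1
    invasive = [t for t in tumors if t.histo_type.is_invasive]

    diameters = np.array([t.diameter_mm for t in invasive if t.diameter_mm is not None], dtype=float)
    if diameters.size:
        q1, med, q3 = (float(v) for v in np.percentile(diameters, [25, 50, 75]))
    else:
        q1 = med = q3 = None

    grade_counts = {g: 0 for g in (1, 2, 3)}
    for t in invasive:
        if t.grade is not None:
            grade_counts[t.grade] += 1

    node_known = [t for t in invasive if t.node_positive is not None]
    node_pos = sum(t.node_positive for t in node_known)

    npis = np.array([t.npi for t in invasive if t.npi is not None], dtype=float)
    npi_cat_counts = {c: 0 for c in ("excellent", "good", "moderate", "poor")}
    for t in invasive:
        cat = t.npi_category
        if cat is not None:
            npi_cat_counts[cat.value] += 1

    return GroupTumorSummary(
        outcome_class=outcome,
        score_group=score_group,
        n=len(tumors),
        histotype_counts=histo_counts,
        n_invasive=len(invasive),
        diameter_median=med,
        diameter_q1=q1,
        diameter_q3=q3,
        diameter_missing=sum(t.diameter_mm is None for t in invasive),
        grade_counts=grade_counts,
        grade_missing=sum(t.grade is None for t in invasive),
        node_positive=Rate(int(node_pos), len(node_known)),
        node_missing=len(invasive) - len(node_known),
        npi_mean=float(npis.mean()) if npis.size else None,
        npi_sd=float(npis.std(ddof=1)) if npis.size > 1 else None,
        npi_missing=len(invasive) - int(npis.size),
        npi_category_counts=npi_cat_counts,
    )


def tumor_summary(exams: Sequence[ScreeningExam]) -> TumorSummary:
    """Histopathology summaries for cancers, split by outcome class and AI
    score 10 versus below 10.

    Medians and interquartile ranges use linear-interpolation quantiles.
    """
    groups: dict[tuple[str, str], GroupTumorSummary] = {}
    for outcome in (OutcomeClass.SCREEN_DETECTED, OutcomeClass.INTERVAL):
        for score_group, keep in (("10", lambda b: b == 10), ("<10", lambda b: b < 10)):
            subset = [e for e in exams if e.outcome_class is outcome and keep(e.ai_bin)]
            groups[(outcome.value, score_group)] = _summarize_group(outcome, score_group, subset)
    return TumorSummary(groups)


# ---------------------------------------------------------------------------
# Prior screening round
# ---------------------------------------------------------------------------


@dataclass
class PriorExamReport:
    """AI score and reader behaviour on the screening round before detection.

    ``table`` has one row per prior-exam AI bin with columns ``n``,
    ``n_consensus``, ``n_recalled``, ``n_pos_one``, ``n_pos_both``.  Summary
    rates share the denominator of cancers with a resolvable prior exam.
    """

    table: pd.DataFrame
    n_with_prior: int
    prior_bin10: Rate
    prior_bin9: Rate
    prior_consensus: Rate
    prior_recalled: Rate
    dangling_prior_ids: list[str]


def prior_exam_analysis(
    exams: Iterable[ScreeningExam], priors: Iterable[ScreeningExam]
) -> PriorExamReport:
    """Distribution of the AI score on prior exams of screen-detected cancers.

    Only screen-detected cancers with a ``prior_exam_id`` that resolves in
    ``priors`` enter the denominator; dangling links are reported and
    excluded.  Because prior exams preceded the detection round, their
    recalls are by construction recalls with a negative outcome.
    """
    prior_by_id = {p.exam_id: p for p in priors}
    cols = ["n", "n_consensus", "n_recalled", "n_pos_one", "n_pos_both"]
    table = pd.DataFrame(0, index=pd.Index(AI_BINS, name="prior_ai_bin"), columns=cols, dtype="int64")
    dangling: list[str] = []
    n = 0
    for exam in exams:
        if exam.outcome_class is not OutcomeClass.SCREEN_DETECTED or exam.prior_exam_id is None:
            continue
        prior = prior_by_id.get(exam.prior_exam_id)
        if prior is None:
            dangling.append(exam.prior_exam_id)
            continue
        n += 1
        b = prior.ai_bin
        table.loc[b, "n"] += 1
        table.loc[b, "n_consensus"] += prior.consensus_flag
        table.loc[b, "n_recalled"] += prior.recall_flag
        npos = int(prior.reader1_score >= 2) + int(prior.reader2_score >= 2)
        if npos == 1:
            table.loc[b, "n_pos_one"] += 1
        elif npos == 2:
            table.loc[b, "n_pos_both"] += 1
    return PriorExamReport(
        table=table,
        n_with_prior=n,
        prior_bin10=Rate(int(table.loc[10, "n"]), n),
        prior_bin9=Rate(int(table.loc[9, "n"]), n),
        prior_consensus=Rate(int(table["n_consensus"].sum()), n),
        prior_recalled=Rate(int(table["n_recalled"].sum()), n),
        dangling_prior_ids=dangling,
    )


# ---------------------------------------------------------------------------
# Pre-screen-reading triage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriageReport:
    """Effect of excluding exams with AI score <= T from the reading stream.

    ``excluded_*`` are rates over the respective totals: all exams
    (workload reduction), screen-detected cancers, interval cancers, and
    recalled exams with a negative outcome ("false positives").  Retained
    counts are the complements, so excluded + retained equals the total in
    every category.
    """

    exclusion_bin: int
    excluded_total: Rate
    excluded_sdc: Rate
    excluded_ic: Rate
    excluded_recalled_negative: Rate

    @property
    def retained_total(self) -> Rate:
        r = self.excluded_total
        return Rate(r.denominator - r.numerator, r.denominator)

    @property
    def retained_sdc(self) -> Rate:
        r = self.excluded_sdc
        return Rate(r.denominator - r.numerator, r.denominator)

    @property
    def retained_ic(self) -> Rate:
        r = self.excluded_ic
        return Rate(r.denominator - r.numerator, r.denominator)

    @property
    def retained_recalled_negative(self) -> Rate:
        r = self.excluded_recalled_negative
        return Rate(r.denominator - r.numerator, r.denominator)


def triage_simulate(exams: Iterable[ScreeningExam], exclusion_bin: int = 5) -> TriageReport:
    """Simulate pre-screen-reading triage at AI score <= ``exclusion_bin``.

    Exams at or below the exclusion bin are removed from the radiologist
    reading stream; the report gives the workload reduction and the share of
    screen-detected cancers, interval cancers and recalled-negative exams
    that the rule would have removed.  ``exclusion_bin=0`` disables triage.
    """
    if not 0 <= exclusion_bin <= 10:
        raise ValueError(f"exclusion bin must lie in 0..10, got {exclusion_bin}")
    tot = {"all": 0, "sdc": 0, "ic": 0, "rn": 0}
    exc = {"all": 0, "sdc": 0, "ic": 0, "rn": 0}

    def bump(key: str, excluded: bool) -> None:
        tot[key] += 1
        exc[key] += excluded

    for exam in exams:
        excluded = exam.ai_bin <= exclusion_bin
        bump("all", excluded)
        if exam.outcome_class is OutcomeClass.SCREEN_DETECTED:
            bump("sdc", excluded)
        elif exam.outcome_class is OutcomeClass.INTERVAL:
            bump("ic", excluded)
        elif exam.recall_flag:
            bump("rn", excluded)
    return TriageReport(
        exclusion_bin=exclusion_bin,
        excluded_total=Rate(exc["all"], tot["all"]),
        excluded_sdc=Rate(exc["sdc"], tot["sdc"]),
        excluded_ic=Rate(exc["ic"], tot["ic"]),
        excluded_recalled_negative=Rate(exc["rn"], tot["rn"]),
    )


def one_reader_only_consensus_share(
    exams: Iterable[ScreeningExam], ai_bin_max: int = 9, ai_bin_min: int = 1
) -> Rate:
    """Share of screen-detected cancers, within an AI-bin range, that were
    forwarded to consensus by exactly one of the two readers.

    The default range (bins 1-9) covers the cancers the AI score-10 rule
    would miss; these are the cases where a single attentive reader made
    the difference.
    """
    num = den = 0
    for exam in exams:
        if exam.outcome_class is not OutcomeClass.SCREEN_DETECTED:
            continue
        if not ai_bin_min <= exam.ai_bin <= ai_bin_max:
            continue
        den += 1
        num += (int(exam.reader1_score >= 2) + int(exam.reader2_score >= 2)) == 1
    return Rate(num, den)
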