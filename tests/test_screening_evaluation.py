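"""Evaluation procedures: confusion accounting, threshold matching,
stratified sensitivity, tumour summaries, prior round, triage."""

import numpy as np
import pytest

from mammoscreen import (
    HistoType,
    OutcomeClass,
    ScreeningExam,
    TumorCharacteristics,
    ai_score10_sensitivity,
    double_reading_confusion,
    matched_specificity_threshold,
    one_reader_only_consensus_share,
    prior_exam_analysis,
    reader_confusion,
    stratified_sensitivity,
    triage_simulate,
    tumor_summary,
)


def make_exam(outcome, r1=1, r2=1, recall=False, ai_raw=0.5, vdg=None, n=[0]):
    n[0] += 1
    outcome = OutcomeClass(outcome)
    return ScreeningExam(
        exam_id=f"t{n[0]}", woman_id=f"tw{n[0]}", age_years=58, screen_year=2014,
        outcome_class=outcome, reader1_score=r1, reader2_score=r2,
        consensus_flag=r1 >= 2 or r2 >= 2, recall_flag=recall,
        ai_raw=ai_raw, ai_bin=max(1, int(np.ceil(ai_raw))), vdg=vdg,
        tumor=TumorCharacteristics(HistoType.INVASIVE_NST) if outcome is not OutcomeClass.NEGATIVE else None,
    )


class TestReaderConfusion:
    def test_direct_enumeration(self):
        exams = [
            make_exam("negative", r1=1), make_exam("negative", r1=1),
            make_exam("negative", r1=2),
            make_exam("screen_detected", r1=2, recall=True),
            make_exam("interval", r1=1),
        ]
        c = reader_confusion(exams, "reader1")
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 2)

    def test_all_negative_reads(self):
        exams = [make_exam("negative"), make_exam("interval")]
        c = reader_confusion(exams, "reader1")
        assert c.sensitivity == 0.0 and c.specificity == 1.0

    def test_all_positive_reads(self):
        exams = [
            make_exam("negative", r1=5, r2=5),
            make_exam("screen_detected", r1=5, r2=5, recall=True),
        ]
        c = reader_confusion(exams, "reader1")
        assert c.sensitivity == 1.0 and c.specificity == 0.0

    def test_second_reader_uses_other_score(self):
        exams = [make_exam("interval", r1=1, r2=3)]
        assert reader_confusion(exams, "reader1").sensitivity == 0.0
        assert reader_confusion(exams, "reader2").sensitivity == 1.0

    def test_empty_class_gives_missing_rate(self):
        c = reader_confusion([make_exam("negative")], "reader1")
        assert c.sensitivity is None and c.specificity == 1.0


class TestDoubleReading:
    def test_vdg4_stratum_sensitivity(self, vdg4_exams):
        c = double_reading_confusion(vdg4_exams)
        assert (c.tp, c.fn) == (59, 35)
        assert c.sensitivity == pytest.approx(0.628, abs=5e-4)

    def test_no_interval_cancers_means_full_sensitivity(self):
        exams = [make_exam("screen_detected", r1=2, recall=True), make_exam("negative")]
        assert double_reading_confusion(exams).sensitivity == 1.0

    def test_overall_study_sensitivity(self, study_exams):
        c = double_reading_confusion(study_exams)
        assert (c.tp, c.fn) == (949, 305)
        assert 100 * c.sensitivity == pytest.approx(75.7, abs=0.05)

    def test_recalled_negatives_are_false_positives(self, study_exams):
        assert double_reading_confusion(study_exams).fp == 9


class TestMatchedSpecificityThreshold:
    def test_uniform_negatives_target_point_eight(self):
        exams = [make_exam("negative", ai_raw=float(v)) for v in range(1, 11)]
        result = matched_specificity_threshold(exams, 0.8)
        assert result.threshold == 8.0
        assert result.achieved_specificity == pytest.approx(0.8)

    def test_target_one_picks_max_negative_score(self):
        exams = [make_exam("negative", ai_raw=v) for v in (0.3, 4.4, 9.9)]
        result = matched_specificity_threshold(exams, 1.0)
        assert result.threshold == 9.9
        assert result.achieved_specificity == 1.0

    def test_sensitivity_counts_cancers_above_threshold(self):
        exams = [make_exam("negative", ai_raw=float(v)) for v in range(1, 11)]
        exams += [make_exam("interval", ai_raw=v) for v in (9.5, 7.0, 3.0)]
        result = matched_specificity_threshold(exams, 0.8)
        assert result.sensitivity_at_threshold == pytest.approx(1 / 3)

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            matched_specificity_threshold([make_exam("negative")], 1.5)

    def test_no_negatives_rejected(self):
        with pytest.raises(ValueError):
            matched_specificity_threshold([make_exam("interval")], 0.5)

    def test_monotone_specificity_and_sensitivity_in_threshold(self):
        rng = np.random.default_rng(11)
        exams = [make_exam("negative", ai_raw=float(r)) for r in rng.uniform(0, 10, 300)]
        exams += [make_exam("interval", ai_raw=float(r)) for r in rng.uniform(2, 10, 60)]
        neg = np.array([e.ai_raw for e in exams if not e.is_cancer])
        can = np.array([e.ai_raw for e in exams if e.is_cancer])
        cuts = np.sort(neg)
        spec = [np.mean(neg <= t) for t in cuts]
        sens = [np.mean(can > t) for t in cuts]
        assert (np.diff(spec) >= 0).all()
        assert (np.diff(sens) <= 0).all()

    def test_agrees_with_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            n_neg = int(rng.integers(1, 400))
            n_can = int(rng.integers(0, 80))
            # ties on purpose: scores on a coarse grid
            neg = rng.integers(0, 40, n_neg) / 4.0
            can = rng.integers(0, 40, n_can) / 4.0
            exams = [make_exam("negative", ai_raw=float(r)) for r in neg]
            exams += [make_exam("interval", ai_raw=float(r)) for r in can]
            target = float(rng.random())
            result = matched_specificity_threshold(exams, target)
            best = None
            for t in sorted(set(neg)):
                s = float(np.mean(neg <= t))
                key = (abs(s - target), -s)
                if best is None or key < best[0]:
                    best = (key, t, s)
            assert result.threshold == best[1]
            assert result.achieved_specificity == pytest.approx(best[2])


class TestAiScore10Sensitivity:
    def test_vdg4_fixture(self, vdg4_exams):
        rate = ai_score10_sensitivity(vdg4_exams, vdg=4)
        assert (rate.numerator, rate.denominator) == (76, 94)
        assert rate.pct == pytest.approx(80.9, abs=0.05)

    def test_all_cancers_at_bin10(self):
        exams = [make_exam("interval", ai_raw=9.7) for _ in range(4)]
        assert ai_score10_sensitivity(exams).value == 1.0

    def test_no_cancers_gives_missing(self):
        assert ai_score10_sensitivity([make_exam("negative")]).value is None

    def test_complement_identity(self, small_cohort):
        rate = ai_score10_sensitivity(small_cohort.exams)
        below = sum(1 for e in small_cohort.exams if e.is_cancer and e.ai_bin < 10)
        assert rate.value == pytest.approx(1 - below / rate.denominator)


class TestStratifiedSensitivity:
    def test_vdg4_row_matches_published_rates(self, vdg4_exams):
        report = stratified_sensitivity(vdg4_exams)
        row = report.strata["vdg4"]
        assert row.double_reading.pct == pytest.approx(62.8, abs=0.05)
        assert row.ai_score10.pct == pytest.approx(80.9, abs=0.05)
        assert (row.n_sdc, row.n_ic) == (59, 35)

    def test_stratum_with_only_negatives_reports_missing(self):
        report = stratified_sensitivity([make_exam("negative", vdg=2)])
        row = report.strata["vdg2"]
        assert row.double_reading.value is None
        assert row.ai_score10.value is None

    def test_pooled_equals_union_of_strata(self, small_cohort):
        report = stratified_sensitivity(small_cohort.exams)
        overall = report.strata["overall"]
        strata = [report.strata[f"vdg{g}"] for g in (1, 2, 3, 4)]
        assert overall.ai_score10.numerator == sum(s.ai_score10.numerator for s in strata)
        assert overall.ai_score10.denominator == sum(s.ai_score10.denominator for s in strata)

    def test_unknown_stratum_collects_exams_without_vdg(self):
        report = stratified_sensitivity([make_exam("interval", ai_raw=9.5, vdg=None)])
        assert report.strata["unknown"].ai_score10.denominator == 1


class TestTumorSummary:
    def test_published_grade_and_node_shares(self, study_exams):
        summary = tumor_summary(study_exams)
        g = summary.group(OutcomeClass.SCREEN_DETECTED, "10")
        assert g.grade_counts == {1: 201, 2: 288, 3: 199}
        assert g.grade_pct[3] == pytest.approx(28.9, abs=0.05)
        assert (g.node_positive.numerator, g.node_positive.denominator) == (148, 688)
        assert g.node_positive.pct == pytest.approx(21.5, abs=0.05)

    def test_published_diameter_quartiles(self, study_exams):
        summary = tumor_summary(study_exams)
        g10 = summary.group(OutcomeClass.SCREEN_DETECTED, "10")
        assert (g10.diameter_q1, g10.diameter_median, g10.diameter_q3) == (10.0, 14.0, 21.0)
        assert g10.diameter_missing == 10
        ic10 = summary.group(OutcomeClass.INTERVAL, "10")
        assert (ic10.diameter_q1, ic10.diameter_median, ic10.diameter_q3) == (13.0, 22.0, 28.0)

    def test_invasive_shares(self, study_exams):
        summary = tumor_summary(study_exams)
        g = summary.group(OutcomeClass.SCREEN_DETECTED, "10")
        assert g.n == 880 and g.n_invasive == 696
        assert g.histotype_counts["dcis"] == 184

    def test_single_tumor_median_equals_value(self):
        exam = make_exam("screen_detected", r1=2, recall=True, ai_raw=9.5)
        exam.tumor.diameter_mm = 14.0
        g = tumor_summary([exam]).group(OutcomeClass.SCREEN_DETECTED, "10")
        assert (g.diameter_q1, g.diameter_median, g.diameter_q3) == (14.0, 14.0, 14.0)

    def test_group_without_invasive_tumors_reports_missing(self):
        exam = make_exam("screen_detected", r1=2, recall=True, ai_raw=9.5)
        exam.tumor = TumorCharacteristics(HistoType.DCIS)
        g = tumor_summary([exam]).group(OutcomeClass.SCREEN_DETECTED, "10")
        assert g.diameter_median is None and g.npi_mean is None
        assert g.node_positive.value is None

    def test_npi_statistics_over_computable_cases(self):
        exams = []
        for d, grade, nodes in ((10.0, 1, 0), (20.0, 2, 2), (60.0, 3, 10)):
            exam = make_exam("interval", ai_raw=9.5)
            exam.tumor = TumorCharacteristics(
                HistoType.INVASIVE_NST, diameter_mm=d, grade=grade, n_positive_nodes=nodes
            )
            exams.append(exam)
        g = tumor_summary(exams).group(OutcomeClass.INTERVAL, "10")
        assert g.npi_mean == pytest.approx(np.mean([2.2, 4.4, 7.2]))
        assert g.npi_category_counts == {"excellent": 1, "good": 0, "moderate": 1, "poor": 1}


class TestPriorExamAnalysis:
    def test_published_prior_rates(self, study_exams, study_priors):
        report = prior_exam_analysis(study_exams, study_priors)
        assert report.n_with_prior == 745
        assert (report.prior_bin10.numerator, report.prior_bin10.pct) == (312, pytest.approx(41.9, abs=0.05))
        assert report.prior_bin9.pct == pytest.approx(15.7, abs=0.05)
        assert report.prior_consensus.numerator == 131
        assert report.prior_consensus.pct == pytest.approx(17.6, abs=0.05)
        assert report.prior_recalled.numerator == 41
        assert report.prior_recalled.pct == pytest.approx(5.5, abs=0.05)

    def test_cancer_without_prior_excluded(self):
        exams = [make_exam("screen_detected", r1=2, recall=True, ai_raw=9.5)]
        report = prior_exam_analysis(exams, [])
        assert report.n_with_prior == 0
        assert report.prior_bin10.value is None

    def test_dangling_link_reported_and_excluded(self):
        exam = make_exam("screen_detected", r1=2, recall=True, ai_raw=9.5)
        exam.prior_exam_id = "nowhere"
        report = prior_exam_analysis([exam], [])
        assert report.dangling_prior_ids == ["nowhere"]
        assert report.n_with_prior == 0


class TestTriage:
    def test_published_exclusions_at_bin_five(self, study_exams):
        report = triage_simulate(study_exams, 5)
        assert report.excluded_total.numerator == 7475
        assert report.excluded_total.pct == pytest.approx(53.8, abs=0.05)
        assert report.excluded_sdc.numerator == 15
        assert report.excluded_sdc.pct == pytest.approx(1.6, abs=0.05)
        assert report.excluded_ic.numerator == 74
        assert report.excluded_ic.pct == pytest.approx(24.3, abs=0.05)

    def test_zero_bin_excludes_nothing(self, vdg4_exams):
        report = triage_simulate(vdg4_exams, 0)
        assert report.excluded_total.numerator == 0
        assert report.retained_total.numerator == len(vdg4_exams)

    def test_conservation_for_all_thresholds(self, study_exams):
        for t in range(0, 11):
            report = triage_simulate(study_exams, t)
            for rate in (
                report.excluded_total, report.excluded_sdc,
                report.excluded_ic, report.excluded_recalled_negative,
            ):
                assert 0 <= rate.numerator <= rate.denominator
            assert report.excluded_total.numerator + report.retained_total.numerator == 13896
            assert report.excluded_sdc.numerator + report.retained_sdc.numerator == 949
            assert report.excluded_ic.numerator + report.retained_ic.numerator == 305

    def test_invalid_bin_rejected(self, vdg4_exams):
        with pytest.raises(ValueError):
            triage_simulate(vdg4_exams, 11)


class TestOneReaderOnlyShare:
    def test_published_share_below_bin10(self, study_exams):
        rate = one_reader_only_consensus_share(study_exams)
        assert (rate.numerator, rate.denominator) == (21, 69)
        assert rate.pct == pytest.approx(30.4, abs=0.05)

    def test_bin10_share(self, study_exams):
        rate = one_reader_only_consensus_share(study_exams, ai_bin_min=10, ai_bin_max=10)
        assert (rate.numerator, rate.denominator) == (194, 880)

    def test_all_both_positive_gives_zero(self):
        exams = [make_exam("screen_detected", r1=3, r2=4, recall=True, ai_raw=4.5)]
        assert one_reader_only_consensus_share(exams).value == 0.0
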