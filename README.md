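# mammoscreen

Evaluation of an AI malignancy score against independent double reading in
cancer-enriched mammography screening cohorts.

## The problem

Population-based screening programmes such as BreastScreen Norway read every
mammogram twice: two radiologists independently assign an interpretation
score 1–5, any exam scored ≥ 2 by either reader is discussed at a consensus
meeting, and consensus decides recall. Commercial AI systems now emit an
exam-level malignancy score — a continuous *raw score* in [0.0, 10.0],
binned into an *AI score* 1–10 (10 = highest risk) — and the question for a
screening programme is how that score compares with its radiologists, and
whether it could triage obviously negative exams out of the reading stream.

`mammoscreen` implements that evaluation for a *cancer-enriched* sample:
every screen-detected cancer (SDC: diagnosed after recall, within 6 months)
and interval cancer (IC: surfacing within 24 months of a negative screen) is
kept and matched to a fixed number of negative exams (1 : 10 by default).
Because prevalence in such a sample is artificial, all sensitivities and
specificities are comparison tools between AI and readers on the same exams,
not population estimates.

## What it computes

- **Score-distribution tables** — exam counts per AI bin × outcome class,
  and per-bin reader behaviour (consensus, recall, positive by one/both
  readers) — plus exact expansion of such printed aggregate tables back into
  exam-level records.
- **Matched-specificity comparison** — the AI raw-score threshold *t* (an
  exam is AI-positive when raw > *t*) whose specificity is closest to a
  target, typically the first reader's, so AI and reader sensitivities are
  compared at the same operating point. Attainable specificities form a
  step function over the distinct negative-exam raw scores; ties go to the
  higher specificity.
- **Density-stratified sensitivity** — first reader, double reading
  (detected = screen-detected) and the "AI score 10" rule per Volpara
  Density Grade (VDG 1–4).
- **Tumour characteristics by AI score** — histotype, diameter median/IQR,
  grade, nodal status and the Nottingham Prognostic Index
  `NPI = 0.2·diameter(cm) + nodal stage (1–3) + grade (1–3)`, categorised
  Excellent ≤ 2.4 < Good ≤ 3.4 < Moderate ≤ 5.4 < Poor.
- **Prior-round analysis** — the AI score and reader behaviour on the
  screening exam *preceding* the one where an SDC was detected.
- **Triage simulation** — workload reduction and missed-cancer fractions if
  exams with AI score ≤ T (default 5) were excluded from human reading.
- **Synthetic cohorts** — a seeded generator of cancer-enriched cohorts
  whose defaults are calibrated to the published tables of the source study,
  so the entire pipeline runs with no access to registry data.

## Worked example

The package ships the source study's aggregate tables
(`mammoscreen.aggregates`) and can expand them into the full 13,896-exam
cohort:

```python
from mammoscreen import aggregates, ai_score10_sensitivity, triage_simulate, prior_exam_analysis
from mammoscreen.cli import render_rate

exams = aggregates.study_exams()            # 13,896 exam-level records
priors = aggregates.study_prior_exams()     # 745 prior-round exams

sdc = [e for e in exams if e.outcome_class.value == "screen_detected"]
ic = [e for e in exams if e.outcome_class.value == "interval"]
print("AI score 10, screen-detected:", render_rate(ai_score10_sensitivity(sdc)))
print("AI score 10, interval:      ", render_rate(ai_score10_sensitivity(ic)))

t = triage_simulate(exams, 5)
print("Triage (AI score <= 5) workload reduction:", render_rate(t.excluded_total))
print("  screen-detected cancers excluded:       ", render_rate(t.excluded_sdc))
print("  interval cancers excluded:              ", render_rate(t.excluded_ic))

p = prior_exam_analysis(exams, priors)
print("AI score 10 on the prior round:", render_rate(p.prior_bin10))
```

prints

```
AI score 10, screen-detected: 92.7% (880/949)
AI score 10, interval:       40.0% (122/305)
Triage (AI score <= 5) workload reduction: 53.8% (7475/13896)
  screen-detected cancers excluded:        1.6% (15/949)
  interval cancers excluded:               24.3% (74/305)
AI score 10 on the prior round: 41.9% (312/745)
```

Reading: 92.7% of screen-detected but only 40.0% of interval cancers sat in
the top AI bin; excluding everything at AI score ≤ 5 would have removed
53.8% of the reading workload at the cost of 1.6% of screen-detected and
24.3% of interval cancers; and 41.9% of screen-detected cancers with an
available prior exam already scored 10 one round before detection.

The same operations are available from the shell:

```bash
mammoscreen simulate --seed 1 --out cohort.csv --priors-out priors.csv
mammoscreen evaluate --in cohort.csv --priors priors.csv --outdir report/
mammoscreen threshold --in cohort.csv --match-first-reader
mammoscreen triage --in cohort.csv --bin 5
mammoscreen npi --in tumors.csv --out tumors_npi.csv
```

## Layout

| module | contents |
| --- | --- |
| `mammoscreen.core_records` | exam/tumour data model, cohort CSV I/O, tabulation, fixture expansion |
| `mammoscreen.clinical_scores` | AI raw-score binning, NPI computation and categorisation |
| `mammoscreen.screening_evaluation` | confusion accounting, threshold matching, stratified sensitivity, tumour summaries, prior-round analysis, triage |
| `mammoscreen.synthetic_cohort` | calibrated seeded cohort generator and parameter recovery |
| `mammoscreen.aggregates` | published aggregate tables and their exam-level expansions |
| `mammoscreen.cli` | `mammoscreen` command-line interface |

See `docs/methods.md` for the modelling assumptions and numerical choices.
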