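# Methods

This note records the statistical procedures implemented in `mammoscreen`,
the assumptions behind them, and the choices made where the published
description of the evaluation leaves the design open.

## Setting and data model

The unit of analysis is a screening examination with:

- an outcome class — *negative*, *screen-detected cancer* (SDC; diagnosed
  after recall within 6 months) or *interval cancer* (IC; diagnosed within
  24 months of a negative screen or 6–24 months after a false positive);
- two independent reader scores 1–5, with the workflow invariants
  `consensus ⇔ (reader1 ≥ 2 or reader2 ≥ 2)`, `recall ⇒ consensus`,
  `SDC ⇒ recall`;
- the AI malignancy raw score in [0.0, 10.0] and its bin 1–10;
- Volpara Density Grade (VDG 1–4, possibly missing);
- histopathology for cancers; and an optional link to the woman's previous
  screening exam.

Reader scores are exam-level. Where source data are per-breast, the
exam-level score is taken as the maximum over breasts before entering this
package; all downstream tables are exam-level. "First reader" means the
`reader1` column — reader order is a property of the input, never inferred.

### AI score binning

The vendor does not publish bin edges for the raw → 1–10 mapping. Bins are
taken as unit intervals closed above, `(k−1, k]`, with 0.0 assigned to
bin 1 — the convention under which "AI score 10" contains the maximal raw
scores. The mapping is monotone and surjective onto 1..10.

### Nottingham Prognostic Index

`NPI = 0.2 × diameter_cm + nodal stage + histologic grade`, with nodal
stage 1 (0 positive nodes), 2 (1–3), 3 (≥ 4). Categories: Excellent ≤ 2.4,
Good ≤ 3.4, Moderate ≤ 5.4, Poor > 5.4, boundaries inclusive on the lower
category. The NPI is computed at full floating precision with no rounding
before categorisation, is defined for invasive tumours only, and requires a
positive-node *count*; a bare binary nodal-status flag feeds the
node-positivity summaries but never the NPI. Missing inputs propagate to a
missing NPI, mirroring "information not available" handling in pathology
tables.

## Evaluation procedures

**Single-reader confusion.** A reader call is positive at score ≥ 2 (the
consensus-forwarding rule). Cancers — SDC and IC alike — with a positive
call are true positives, including cancers recalled earlier with a negative
assessment; missed cancers are false negatives; negative-outcome exams with
a positive call are false positives.

**Double-reading (programme-level) confusion.** Detection means actual
detection: SDC are true positives, all IC are misses even if discussed at
consensus or recalled, and recalled negatives are the false positives. The
two accounting rules intentionally differ — the single-reader rule scores a
reader's *suspicion*, the programme rule scores the programme's *result* —
and both are exposed as separate operations.

**Matched-specificity threshold.** An exam is AI-positive when
`raw > t`. On a finite sample the attainable specificities form a step
function whose jumps sit at the distinct negative-exam raw scores; these
are the candidate cuts. The cut whose specificity is closest to the target
is returned, ties broken toward the higher specificity (the published
procedure asks for the "exact same" specificity as the first reader, which
is generally unattainable on a step function; closest-attainable with a
deterministic tie rule is this package's resolution). Sensitivity at the
cut counts all cancers above it.

**AI-score-10 sensitivity** is simply the share of cancers in bin 10,
overall or within a VDG stratum; undefined rates (zero denominators) are
reported as missing, never as zero.

**Tumour summaries** are computed per outcome class × (AI score 10 vs
below 10) for invasive tumours: diameter median/IQR via
linear-interpolation quantiles (no quantile rule is published; this is the
numpy default and the most common convention), grade and nodal percentages
over non-missing denominators with missing counts reported separately, and
NPI mean/SD/categories over the cases where the index is computable.

**Prior-round analysis** restricts to screen-detected cancers whose prior
exam link resolves; dangling links are reported and excluded from the
denominator. Prior exams are negative screens by construction, so their
recalls are recalls with negative outcome.

**Triage simulation** removes exams with AI bin ≤ T (default 5) from the
reading stream and reports the excluded fraction overall and within SDC,
IC and recalled negatives, with the conservation invariant excluded +
retained = total in every category.

## Expansion of printed aggregate tables

The exam-level data behind the source evaluation are not public; its
aggregate tables are. `expand_fixture` reconstructs minimal exam-level
records whose re-tabulation reproduces a printed table exactly: raw scores
at bin midpoints (bin − 0.5; every fixture-based quantity depends only on
bins), reader splits dealt out deterministically in bin order ("one
positive" → scores (2, 1), "both" → (2, 2)), recalled negatives drawn from
the negative class of the same bin. The published tables satisfy, bin by
bin, `recalled = SDC + recalled-negative`; the expansion enforces that
convention (interval cancers are not recalled at the index screen) and
rejects contradictory aggregates.

For the tumour tables, histotype/grade/nodal status are dealt out to match
the printed counts exactly. Diameters of the non-missing invasive tumours
cycle through (q1, median, q3): each value then occupies one third of the
sorted sample, so linear-interpolation quantiles reproduce the printed
median and IQR exactly. This is an expansion device, not a claim about the
real diameter distribution. Nodal status is stored as the binary flag only
(no counts are printed), so NPI values are deliberately uncomputable in the
expanded fixture; NPI machinery is exercised by unit tests and synthetic
cohorts instead.

Two inconsistencies in the printed sources are resolved as follows: the
prior-exam table's heading count (754) disagrees with its total row and the
running text (745) — the internally consistent 745 is used; and the rounded
VDG shares 15/49/30/7% sum to 101%, so probability vectors are normalised
from the underlying counts (1916/6111/3782/891).

## Synthetic cohort generator

The generator emulates the sampling design: exact class counts, with
`controls_per_cancer` (default 10) negatives per cancer — a matched design,
not a draw. Conditional structure per exam:

1. age ~ Normal(58, 6), rounded and clipped to 50–74; screening year
   uniform 2010–2018;
2. VDG from the marginal density distribution;
3. AI bin from the outcome class's 10-vector (defaults = the published
   per-class distributions). For cancer classes a per-VDG override of
   P(bin 10) applies — defaults: SDC with VDG 4 → 1.0, IC with VDG 4 →
   0.486 — with the remaining mass spread over bins 1–9 proportionally to
   the class distribution;
4. raw score uniform within the bin's interval (no within-bin shape is
   published);
5. reader behaviour per class × bin from the published reader-workflow
   proportions (SDC always recalled; IC never recalled at the index
   screen; negatives reach consensus, and within consensus recall, at the
   published per-bin rates); positive reader scores uniform on 2–5;
6. tumour per class × score group: histotype multinomial; diameter
   log-normal with location `ln(median)` and scale `ln(q3/q1)/(2 z₀.₇₅)`
   solved in closed form from the printed median and IQR; grade
   multinomial; binary nodal status, with positive cases given
   1 + Poisson(1.2) positive nodes so the NPI is computable; per-field
   missingness at the printed rates;
7. for screen-detected cancers, a prior exam with probability 745/949,
   its bin, consensus, reader-split and recall drawn from the published
   prior-round proportions.

A single pseudo-random stream is consumed in a documented order (SDC, IC,
negatives; fixed per-exam draw sequence), so at a fixed seed enlarging a
later class never perturbs earlier records, and every generated record
satisfies the exam invariants by construction.

`recover_parameters` recomputes the empirical counterpart of each
configured proportion with its binomial standard error at the configured
value. For cancer classes the bin multinomial is estimated within VDG
strata that carry no score-10 override (where the class distribution
applies unchanged), and the override is checked as the bin-10 share within
its stratum. With 10⁴ exams per class every configured proportion is
recovered within 4 standard errors.

### What the generator does and does not emulate

It reproduces the *marginal* calibration targets (bin, VDG, reader, tumour
and prior-round distributions) and the conditional links listed above.  It
does **not** model: correlation between density and tumour size (masking),
reader-score magnitudes beyond positive/negative, within-bin raw-score
shape, the matching algorithm on age/year (only the count bookkeeping), or
the source study's exclusion path from 1275/12,750 sampled to 1254/12,642
analysed. Consequently, passing pipeline tests on synthetic cohorts shows
the procedures are correct and closed over realistic inputs — not that the
generator reproduces exam-level operating points of the real AI system. In
particular, the matched-specificity sensitivity on synthetic cohorts is far
below the real system's, because a uniform within-bin raw score carries no
ranking information inside bin 10, where most cancers sit. The published
reader-versus-AI operating points (97.6%/68.6%/68.3%) and the
false-positive triage fraction (whose 568-exam denominator is not
derivable from the printed tables) therefore cannot be, and are not,
reproduced quantitatively.

## Numerical and reporting conventions

- Rates are carried as numerator/denominator pairs; zero denominators give
  missing rates, rendered as "–".
- Display rounding is one decimal, half away from zero, in the
  `x% (a/b)` style; tests compare unrounded values with a tolerance of
  0.05 percentage points against values printed to one decimal.
- Cohort CSVs are UTF-8 with a fixed column order, booleans as 0/1 and
  missing values as empty strings; floats are written with `repr` so a
  write–read–write cycle is byte-identical.
- Problem sizes: the test suite runs the full 13,896-exam fixture cohort,
  100 random cohorts of up to ~1,000 exams for the brute-force threshold
  check, and synthetic cohorts of up to 10⁴ exams per class for parameter
  recovery; the acceptance script uses the fixture cohort plus a
  949/305/2× synthetic cohort.

## Known limitations

- The fixture expansion assigns unspecified fields (age, year, which exams
  within a bin carry which tumour) deterministically; any quantity
  depending on those joints is not meaningful on fixtures.
- NPI summaries on the fixture cohort are empty by design (no printed node
  counts); the published NPI means/SDs are generator calibration targets
  only in the sense of category multinomials, not reproduced statistics.
- The generator's VDG distribution is shared across outcome classes; the
  true class-conditional density distributions are not published in full.
- Specificity-matched comparisons on cancer-enriched samples do not
  transfer to population screening; the package reports them as
  within-sample comparisons only.
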