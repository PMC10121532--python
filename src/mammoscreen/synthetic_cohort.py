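"""Seeded generator of cancer-enriched screening cohorts.

Emulates the sampling design of the source evaluation: every screen-detected
and interval cancer is kept and matched with a fixed number of negative
examinations (1 cancer : 10 matched negatives by default), so cancer
prevalence in generated cohorts is far above the screening population's —
exactly the condition under which the evaluation's sensitivities and
specificities are comparison tools rather than population estimates.

The default configuration is calibrated to the published aggregate tables
carried by :mod:`mammoscreen.aggregates`: AI-bin distributions per outcome
class, marginal VDG shares, a VDG4 up-weighting of AI score 10 for cancers,
per-bin reader behaviour, histotype/grade/nodal/diameter models per outcome
class and AI score group (with the published missingness), and a prior-round
model for screen-detected cancers.

The conditional structure is ``vdg -> ai_bin -> reader behaviour | (class,
bin) -> tumour | (class, score group)``; no further dependencies are
modelled.  A single pseudo-random stream is consumed in documented order
(screen-detected cancers, interval cancers, negatives; fixed per-exam draw
sequence), so at a fixed seed, enlarging a later class never perturbs
earlier records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from . import aggregates
from .core_records import HistoType, OutcomeClass, ScreeningExam, TumorCharacteristics

__all__ = [
    "ConfigError",
    "TumorModel",
    "ReaderBehavior",
    "PriorModel",
    "GeneratorConfig",
    "SyntheticCohort",
    "default_config",
    "generate_cohort",
    "recover_parameters",
    "RecoveredProportion",
    "RecoveryReport",
]

_Z75 = 0.6744897501960817  # 75th normal percentile; turns an IQR into a log-normal scale

_CANCER_CLASSES = ("screen_detected", "interval")
_CLASSES = ("negative",) + _CANCER_CLASSES
_HISTO_ORDER = (
    HistoType.DCIS,
    HistoType.INVASIVE_NST,
    HistoType.INVASIVE_LOBULAR,
    HistoType.OTHER_INVASIVE,
)


class ConfigError(ValueError):
    """Raised when a generator configuration is inconsistent or infeasible."""


def _check_probs(name: str, probs: Sequence[float], length: int) -> None:
    if len(probs) != length:
        raise ConfigError(f"{name} must have {length} entries, got {len(probs)}")
    if any(p < 0 for p in probs):
        raise ConfigError(f"{name} has negative entries: {probs}")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigError(f"{name} must sum to 1 +- 1e-9, got {sum(probs)}")


@dataclass(frozen=True)
class TumorModel:
    """Histopathology model for one outcome class x AI score group.

    Diameters are log-normal with parameters solved in closed form from the
    published median and IQR: the location is ``ln(median)`` and the scale
    is ``ln(q3/q1) / (2 z_0.75)``.  Nodal involvement is drawn as a binary
    status; positive cases receive a positive-node count (1 plus a Poisson
    excess) so the NPI is computable.  Missingness is per-field Bernoulli.
    """

    histotype_probs: tuple[float, float, float, float]
    diameter_median: float
    diameter_q1: float
    diameter_q3: float
    p_diameter_missing: float
    grade_probs: tuple[float, float, float]
    p_grade_missing: float
    p_node_positive: float
    p_node_missing: float
    extra_nodes_mean: float = 1.2

    def validate(self, name: str) -> None:
        _check_probs(f"{name}.histotype_probs", self.histotype_probs, 4)
        _check_probs(f"{name}.grade_probs", self.grade_probs, 3)
        if not 0 < self.diameter_q1 <= self.diameter_median <= self.diameter_q3:
            raise ConfigError(f"{name}: diameter quartiles must satisfy 0 < q1 <= median <= q3")
        for p_name in ("p_diameter_missing", "p_grade_missing", "p_node_positive", "p_node_missing"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}.{p_name} must lie in [0, 1], got {p}")

    @property
    def log_sigma(self) -> float:
        return math.log(self.diameter_q3 / self.diameter_q1) / (2.0 * _Z75) if self.diameter_q3 > self.diameter_q1 else 0.0

    @property
    def log_mu(self) -> float:
        return math.log(self.diameter_median)


@dataclass(frozen=True)
class ReaderBehavior:
    """Per-AI-bin reader behaviour for one outcome class.

    For screen-detected cancers ``p_pos_one`` is the probability that
    exactly one reader is positive (otherwise both; every screen-detected
    cancer is consensus-discussed and recalled).  For interval cancers
    ``p_pos_one``/``p_pos_both`` give the chance of one/both positive
    readers at the index screen (otherwise both negative; never recalled).
    For negatives ``p_consensus`` is the chance of consensus discussion and
    ``p_recall_given_consensus`` the chance of a (negative-outcome) recall
    within consensus.
    """

    p_pos_one: tuple[float, ...] = (0.0,) * 10
    p_pos_both: tuple[float, ...] = (0.0,) * 10
    p_consensus: tuple[float, ...] = (0.0,) * 10
    p_recall_given_consensus: tuple[float, ...] = (0.0,) * 10

    def validate(self, name: str) -> None:
        for attr in ("p_pos_one", "p_pos_both", "p_consensus", "p_recall_given_consensus"):
            probs = getattr(self, attr)
            if len(probs) != 10:
                raise ConfigError(f"{name}.{attr} must have 10 entries")
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ConfigError(f"{name}.{attr} entries must lie in [0, 1]")
        if any(a + b > 1.0 + 1e-9 for a, b in zip(self.p_pos_one, self.p_pos_both)):
            raise ConfigError(f"{name}: p_pos_one + p_pos_both exceeds 1 in some bin")


@dataclass(frozen=True)
class PriorModel:
    """Prior-round model for screen-detected cancers."""

    p_available: float
    bin_probs: tuple[float, ...]
    p_consensus: tuple[float, ...]
    p_pos_both_given_consensus: tuple[float, ...]
    p_recall_given_consensus: tuple[float, ...]

    def validate(self, name: str) -> None:
        if not 0.0 <= self.p_available <= 1.0:
            raise ConfigError(f"{name}.p_available must lie in [0, 1]")
        _check_probs(f"{name}.bin_probs", self.bin_probs, 10)
        for attr in ("p_consensus", "p_pos_both_given_consensus", "p_recall_given_consensus"):
            probs = getattr(self, attr)
            if len(probs) != 10 or any(not 0.0 <= p <= 1.0 for p in probs):
                raise ConfigError(f"{name}.{attr} must be 10 probabilities in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cancer-enriched cohort.

    ``ai_bin_probs`` maps each outcome class to its 10-vector of AI-bin
    probabilities.  ``score10_given_vdg`` optionally overrides, per cancer
    class and VDG, the probability of AI score 10 (``None`` leaves the class
    distribution untouched); the remaining mass is spread over bins 1-9
    proportionally to the class distribution.
    """

    n_sdc: int = 949
    n_ic: int = 305
    controls_per_cancer: int = 10
    age_mean: float = 58.0
    age_sd: float = 6.0
    year_min: int = 2010
    year_max: int = 2018
    vdg_probs: tuple[float, float, float, float] = aggregates.VDG_DISTRIBUTION
    ai_bin_probs: dict[str, tuple[float, ...]] = field(default_factory=dict)
    score10_given_vdg: dict[str, tuple[Optional[float], ...]] = field(default_factory=dict)
    reader_behavior: dict[str, ReaderBehavior] = field(default_factory=dict)
    tumor_models: dict[tuple[str, str], TumorModel] = field(default_factory=dict)
    prior_model: Optional[PriorModel] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_sdc < 0 or self.n_ic < 0 or self.controls_per_cancer < 0:
            raise ConfigError("class counts must be non-negative")
        if self.age_sd < 0:
            raise ConfigError("age_sd must be non-negative")
        if self.year_max < self.year_min:
            raise ConfigError("year_max must be >= year_min")
        _check_probs("vdg_probs", self.vdg_probs, 4)
        for cls in _CLASSES:
            if cls not in self.ai_bin_probs:
                raise ConfigError(f"ai_bin_probs missing class {cls!r}")
            _check_probs(f"ai_bin_probs[{cls!r}]", self.ai_bin_probs[cls], 10)
            if cls not in self.reader_behavior:
                raise ConfigError(f"reader_behavior missing class {cls!r}")
            self.reader_behavior[cls].validate(f"reader_behavior[{cls!r}]")
        for cls, adj in self.score10_given_vdg.items():
            if cls not in _CANCER_CLASSES:
                raise ConfigError(f"score10_given_vdg only applies to cancer classes, got {cls!r}")
            if len(adj) != 4:
                raise ConfigError(f"score10_given_vdg[{cls!r}] must have 4 entries")
            p10 = self.ai_bin_probs[cls][9]
            for a in adj:
                if a is None:
                    continue
                if not 0.0 <= a <= 1.0:
                    raise ConfigError(f"score10_given_vdg[{cls!r}] entries must lie in [0, 1]")
                if a < 1.0 and p10 >= 1.0:
                    raise ConfigError(
                        f"score10_given_vdg[{cls!r}]: cannot spread mass over bins 1-9 "
                        "when the class distribution has all mass on bin 10"
                    )
        for cls in _CANCER_CLASSES:
            for group in ("10", "<10"):
                key = (cls, group)
                if key not in self.tumor_models:
                    raise ConfigError(f"tumor_models missing group {key}")
                self.tumor_models[key].validate(f"tumor_models[{key}]")
        if self.prior_model is not None:
            self.prior_model.validate("prior_model")


def _ratio_vec(num: Sequence[int], den: Sequence[int]) -> tuple[float, ...]:
    return tuple((n / d if d else 0.0) for n, d in zip(num, den))


def default_config() -> GeneratorConfig:
    """The configuration calibrated to the published study tables.

    Every default is taken from the aggregate counts in
    :mod:`mammoscreen.aggregates`: class sizes and AI-bin distributions from
    the exam-count grid, reader behaviour from the reader-workflow grid,
    the VDG marginals and the VDG4 score-10 shares (all screen-detected,
    48.6% of interval cancers) from the density results, tumour models from
    the histopathology tables, and the prior-round model from the
    prior-exam grid.
    """
    sc = aggregates.SCORE_OUTCOME_COUNTS
    rc = aggregates.READER_OUTCOME_COUNTS
    n_neg = [int(v) for v in sc["negative"]]
    n_sdc = [int(v) for v in sc["screen_detected"]]
    n_ic = [int(v) for v in sc["interval"]]

    ai_bin_probs = {
        cls: tuple(v / sum(sc[cls]) for v in sc[cls]) for cls in _CLASSES
    }

    ic_cons = [o + b for o, b in zip(rc["n_ic_pos_one"], rc["n_ic_pos_both"])]
    neg_cons = [
        c - s - i for c, s, i in zip(rc["n_consensus"], n_sdc, ic_cons)
    ]
    reader_behavior = {
        "screen_detected": ReaderBehavior(
            p_pos_one=_ratio_vec(rc["n_sdc_pos_one"], n_sdc),
            p_pos_both=_ratio_vec(rc["n_sdc_pos_both"], n_sdc),
        ),
        "interval": ReaderBehavior(
            p_pos_one=_ratio_vec(rc["n_ic_pos_one"], n_ic),
            p_pos_both=_ratio_vec(rc["n_ic_pos_both"], n_ic),
        ),
        "negative": ReaderBehavior(
            p_consensus=_ratio_vec(neg_cons, n_neg),
            p_recall_given_consensus=_ratio_vec(rc["n_recalled_negative"], neg_cons),
        ),
    }

    tumor_models: dict[tuple[str, str], TumorModel] = {}
    for key, histo in aggregates.HISTOTYPE_COUNTS.items():
        path = aggregates.INVASIVE_PATHOLOGY[key]
        n_all = sum(histo.values())
        n_inv = path["n"]
        g = path["grade"]
        d = path["diameter"]
        nodes = path["nodes"]
        grade_known = sum(g["counts"])
        node_known = n_inv - nodes["missing"]
        tumor_models[key] = TumorModel(
            histotype_probs=tuple(histo[h] / n_all for h in _HISTO_ORDER),
            diameter_median=d["median"],
            diameter_q1=d["q1"],
            diameter_q3=d["q3"],
            p_diameter_missing=d["missing"] / n_inv,
            grade_probs=tuple(c / grade_known for c in g["counts"]),
            p_grade_missing=g["missing"] / n_inv,
            p_node_positive=nodes["positive"] / node_known,
            p_node_missing=nodes["missing"] / n_inv,
        )

    pc = aggregates.PRIOR_EXAM_COUNTS
    n_prior = sum(pc["n"])
    prior_model = PriorModel(
        p_available=n_prior / sum(sc["screen_detected"]),
        bin_probs=tuple(v / n_prior for v in pc["n"]),
        p_consensus=_ratio_vec(pc["n_consensus"], pc["n"]),
        p_pos_both_given_consensus=_ratio_vec(pc["n_pos_both"], pc["n_consensus"]),
        p_recall_given_consensus=_ratio_vec(pc["n_recalled"], pc["n_consensus"]),
    )

    config = GeneratorConfig(
        ai_bin_probs=ai_bin_probs,
        score10_given_vdg={
            "screen_detected": (None, None, None, 1.0),
            "interval": (None, None, None, 0.486),
        },
        reader_behavior=reader_behavior,
        tumor_models=tumor_models,
        prior_model=prior_model,
    )
    config.validate()
    return config


@dataclass
class SyntheticCohort:
    """A generated cohort: index exams plus prior-round exams.

    Iterating the cohort iterates the index exams; prior exams (negative
    screens of women later diagnosed) live in ``priors`` and are linked via
    ``prior_exam_id``.
    """

    exams: list[ScreeningExam]
    priors: list[ScreeningExam]

    def __iter__(self) -> Iterator[ScreeningExam]:
        return iter(self.exams)

    def __len__(self) -> int:
        return len(self.exams)


def _bin_probs_for(config: GeneratorConfig, cls: str, vdg: int) -> np.ndarray:
    probs = np.asarray(config.ai_bin_probs[cls], dtype=float)
    adj = config.score10_given_vdg.get(cls)
    if adj is None or adj[vdg - 1] is None:
        return probs
    a = float(adj[vdg - 1])
    p10 = probs[9]
    out = probs.copy()
    if a >= 1.0:
        out[:9] = 0.0
    else:
        out[:9] *= (1.0 - a) / (1.0 - p10)
    out[9] = a
    return out


def _draw_tumor(rng: np.random.Generator, model: TumorModel) -> TumorCharacteristics:
    histo = _HISTO_ORDER[rng.choice(4, p=np.asarray(model.histotype_probs))]
    if not histo.is_invasive:
        return TumorCharacteristics(histo_type=histo)
    diameter: Optional[float] = None
    if rng.random() >= model.p_diameter_missing:
        diameter = float(
            max(1.0, round(math.exp(model.log_mu + model.log_sigma * rng.standard_normal()), 1))
        )
    grade: Optional[int] = None
    if rng.random() >= model.p_grade_missing:
        grade = 1 + int(rng.choice(3, p=np.asarray(model.grade_probs)))
    n_nodes: Optional[int] = None
    if rng.random() >= model.p_node_missing:
        if rng.random() < model.p_node_positive:
            n_nodes = 1 + int(rng.poisson(model.extra_nodes_mean))
        else:
            n_nodes = 0
    return TumorCharacteristics(
        histo_type=histo, diameter_mm=diameter, grade=grade, n_positive_nodes=n_nodes
    )


def generate_cohort(config: GeneratorConfig, seed: Optional[int] = None) -> SyntheticCohort:
    """Generate a cohort satisfying every exam-record invariant by construction.

    Class counts are exact (matched design): ``n_sdc`` screen-detected,
    ``n_ic`` interval, ``controls_per_cancer x (n_sdc + n_ic)`` negatives.
    ``seed`` overrides ``config.seed``; two runs at the same seed produce
    identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_controls = config.controls_per_cancer * (config.n_sdc + config.n_ic)
    exams: list[ScreeningExam] = []
    priors: list[ScreeningExam] = []
    vdg_p = np.asarray(config.vdg_probs, dtype=float)
    serial = 0

    def draw_positive_score() -> int:
        return int(rng.integers(2, 6))

    def draw_reader_pair(npos: int) -> tuple[int, int]:
        if npos == 0:
            return 1, 1
        if npos == 2:
            return draw_positive_score(), draw_positive_score()
        if rng.random() < 0.5:
            return draw_positive_score(), 1
        return 1, draw_positive_score()

    def make_exam(cls: str) -> ScreeningExam:
        nonlocal serial
        serial += 1
        age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 50, 74))
        year = int(rng.integers(config.year_min, config.year_max + 1))
        vdg = 1 + int(rng.choice(4, p=vdg_p))
        bin_ = 1 + int(rng.choice(10, p=_bin_probs_for(config, cls, vdg)))
        ai_raw = bin_ - float(rng.random())  # uniform within (bin-1, bin]
        behavior = config.reader_behavior[cls]
        i = bin_ - 1
        tumor: Optional[TumorCharacteristics] = None
        recall = False
        if cls == "screen_detected":
            npos = 1 if rng.random() < behavior.p_pos_one[i] else 2
            recall = True
        elif cls == "interval":
            u = rng.random()
            if u < behavior.p_pos_one[i]:
                npos = 1
            elif u < behavior.p_pos_one[i] + behavior.p_pos_both[i]:
                npos = 2
            else:
                npos = 0
        else:
            npos = 0
            if rng.random() < behavior.p_consensus[i]:
                npos = 1
                recall = rng.random() < behavior.p_recall_given_consensus[i]
        r1, r2 = draw_reader_pair(npos)
        if cls in _CANCER_CLASSES:
            group = "10" if bin_ == 10 else "<10"
            tumor = _draw_tumor(rng, config.tumor_models[(cls, group)])
        exam = ScreeningExam(
            exam_id=f"syn-{serial:07d}",
            woman_id=f"syn-w-{serial:07d}",
            age_years=age,
            screen_year=year,
            outcome_class=OutcomeClass(cls),
            reader1_score=r1,
            reader2_score=r2,
            consensus_flag=r1 >= 2 or r2 >= 2,
            recall_flag=recall,
            ai_raw=ai_raw,
            ai_bin=bin_,
            vdg=vdg,
            tumor=tumor,
        )
        if cls == "screen_detected" and config.prior_model is not None:
            pm = config.prior_model
            if rng.random() < pm.p_available:
                pb = 1 + int(rng.choice(10, p=np.asarray(pm.bin_probs)))
                j = pb - 1
                p_npos = 0
                p_recall = False
                if rng.random() < pm.p_consensus[j]:
                    p_npos = 2 if rng.random() < pm.p_pos_both_given_consensus[j] else 1
                    p_recall = rng.random() < pm.p_recall_given_consensus[j]
                pr1, pr2 = draw_reader_pair(p_npos)
                prior = ScreeningExam(
                    exam_id=f"syn-prior-{serial:07d}",
                    woman_id=exam.woman_id,
                    age_years=max(50, age - 2),
                    screen_year=max(config.year_min, year - 2),
                    outcome_class=OutcomeClass.NEGATIVE,
                    reader1_score=pr1,
                    reader2_score=pr2,
                    consensus_flag=pr1 >= 2 or pr2 >= 2,
                    recall_flag=p_recall,
                    ai_raw=pb - float(rng.random()),
                    ai_bin=pb,
                )
                priors.append(prior)
                exam.prior_exam_id = prior.exam_id
        return exam

    for _ in range(config.n_sdc):
        exams.append(make_exam("screen_detected"))
    for _ in range(config.n_ic):
        exams.append(make_exam("interval"))
    for _ in range(n_controls):
        exams.append(make_exam("negative"))
    return SyntheticCohort(exams=exams, priors=priors)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveredProportion:
    """One configured proportion and its empirical estimate.

    ``se`` is the binomial standard error at the configured value; ``z`` is
    the standardised deviation (``None`` when the estimate is undefined, and
    0/inf for degenerate configured values depending on exact agreement).
    """

    name: str
    configured: float
    estimate: Optional[float]
    n: int

    @property
    def se(self) -> Optional[float]:
        if self.n == 0:
            return None
        return math.sqrt(self.configured * (1.0 - self.configured) / self.n)

    @property
    def z(self) -> Optional[float]:
        if self.estimate is None:
            return None
        se = self.se
        if se is None:
            return None
        if se == 0.0:
            return 0.0 if self.estimate == self.configured else math.inf
        return (self.estimate - self.configured) / se


@dataclass
class RecoveryReport:
    """Empirical proportions of a generated cohort versus its configuration."""

    entries: list[RecoveredProportion]

    def max_abs_z(self) -> float:
        zs = [abs(e.z) for e in self.entries if e.z is not None]
        return max(zs) if zs else 0.0

    def within(self, n_se: float) -> bool:
        return all(e.z is None or abs(e.z) <= n_se for e in self.entries)


def _prop(name: str, configured: float, hits: int, n: int) -> RecoveredProportion:
    return RecoveredProportion(
        name=name, configured=configured, estimate=(hits / n if n else None), n=n
    )


def recover_parameters(cohort: SyntheticCohort, config: GeneratorConfig) -> RecoveryReport:
    """Recompute the empirical counterparts of the configured proportions.

    Covers the VDG marginal, the per-class AI-bin multinomials (for cancer
    classes, estimated within VDG strata that carry no score-10 adjustment,
    where the class distribution applies unchanged), the score-10 shares in
    adjusted strata, per-bin reader behaviour, histotype/grade multinomials,
    nodal positivity and missingness, and prior-exam availability and bin
    distribution.  Classes or cells with no exams report a missing estimate
    rather than dividing by zero.
    """
    entries: list[RecoveredProportion] = []
    exams = cohort.exams

    for k in range(4):
        entries.append(
            _prop(f"vdg[{k + 1}]", config.vdg_probs[k], sum(e.vdg == k + 1 for e in exams), len(exams))
        )

    for cls in _CLASSES:
        members = [e for e in exams if e.outcome_class.value == cls]
        adj = config.score10_given_vdg.get(cls, (None,) * 4)
        unadjusted = [e for e in members if adj[e.vdg - 1] is None]
        for b in range(1, 11):
            entries.append(
                _prop(
                    f"ai_bin[{cls}][{b}]",
                    config.ai_bin_probs[cls][b - 1],
                    sum(e.ai_bin == b for e in unadjusted),
                    len(unadjusted),
                )
            )
        for k in range(4):
            if adj[k] is None:
                continue
            stratum = [e for e in members if e.vdg == k + 1]
            entries.append(
                _prop(
                    f"score10_given_vdg[{cls}][{k + 1}]",
                    float(adj[k]),
                    sum(e.ai_bin == 10 for e in stratum),
                    len(stratum),
                )
            )
        behavior = config.reader_behavior[cls]
        for b in range(1, 11):
            in_bin = [e for e in members if e.ai_bin == b]
            npos = [int(e.reader1_score >= 2) + int(e.reader2_score >= 2) for e in in_bin]
            if cls == "screen_detected":
                entries.append(
                    _prop(f"sdc_pos_one[{b}]", behavior.p_pos_one[b - 1], sum(x == 1 for x in npos), len(in_bin))
                )
            elif cls == "interval":
                entries.append(
                    _prop(f"ic_pos_one[{b}]", behavior.p_pos_one[b - 1], sum(x == 1 for x in npos), len(in_bin))
                )
                entries.append(
                    _prop(f"ic_pos_both[{b}]", behavior.p_pos_both[b - 1], sum(x == 2 for x in npos), len(in_bin))
                )
            else:
                cons = [e for e in in_bin if e.consensus_flag]
                entries.append(
                    _prop(f"neg_consensus[{b}]", behavior.p_consensus[b - 1], len(cons), len(in_bin))
                )
                entries.append(
                    _prop(
                        f"neg_recall_given_consensus[{b}]",
                        behavior.p_recall_given_consensus[b - 1],
                        sum(e.recall_flag for e in cons),
                        len(cons),
                    )
                )

    for (cls, group), model in config.tumor_models.items():
        members = [
            e
            for e in exams
            if e.outcome_class.value == cls
            and ((e.ai_bin == 10) == (group == "10"))
            and e.tumor is not None
        ]
        tumors = [e.tumor for e in members]
        for h, p in zip(_HISTO_ORDER, model.histotype_probs):
            entries.append(
                _prop(
                    f"histotype[{cls},{group}][{h.value}]",
                    p,
                    sum(t.histo_type is h for t in tumors),
                    len(tumors),
                )
            )
        invasive = [t for t in tumors if t.histo_type.is_invasive]
        graded = [t for t in invasive if t.grade is not None]
        for g, p in zip((1, 2, 3), model.grade_probs):
            entries.append(
                _prop(f"grade[{cls},{group}][{g}]", p, sum(t.grade == g for t in graded), len(graded))
            )
        entries.append(
            _prop(
                f"grade_missing[{cls},{group}]",
                model.p_grade_missing,
                sum(t.grade is None for t in invasive),
                len(invasive),
            )
        )
        node_known = [t for t in invasive if t.node_positive is not None]
        entries.append(
            _prop(
                f"node_positive[{cls},{group}]",
                model.p_node_positive,
                sum(bool(t.node_positive) for t in node_known),
                len(node_known),
            )
        )
        entries.append(
            _prop(
                f"diameter_missing[{cls},{group}]",
                model.p_diameter_missing,
                sum(t.diameter_mm is None for t in invasive),
                len(invasive),
            )
        )

    if config.prior_model is not None:
        pm = config.prior_model
        sdc = [e for e in exams if e.outcome_class is OutcomeClass.SCREEN_DETECTED]
        entries.append(
            _prop("prior_available", pm.p_available, sum(e.prior_exam_id is not None for e in sdc), len(sdc))
        )
        for b in range(1, 11):
            entries.append(
                _prop(
                    f"prior_bin[{b}]",
                    pm.bin_probs[b - 1],
                    sum(p.ai_bin == b for p in cohort.priors),
                    len(cohort.priors),
                )
            )
    return RecoveryReport(entries=entries)
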