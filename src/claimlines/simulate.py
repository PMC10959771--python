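"""Synthetic SNDS-like claims generator with planted ground truth.

Real nationwide claims are not redistributable, so analyses here are
exercised on synthetic patient bundles that reproduce the *structure* the
pipeline assumes: per-patient dated drug dispensings (oral endocrine
therapy, CDK4/6 inhibitors, fulvestrant, chemotherapy), ICD-10 diagnosis
streams including secondary-malignancy and comorbidity codes, death records,
and a 2014–2019 observation window with a three-year lookback.

Each patient receives an index date uniform over the accrual window, a
first-line CDK4/6 inhibitor + endocrine-partner regimen realised as monthly
refills (the final fill truncated to the planned stop date), optional
subsequent lines after a between-line gap, lookback exposures, comorbidity
and metastasis codes, and an exponential death time; everything is truncated
at death and at the administrative cutoff.  Default parameters are set to
the observable marginals of published French real-world CDK4/6-inhibitor
use (arm mix 67/33, first-line median durations 17.3 / 9.7 months, lookback
AI exposure 29.6% / 72.3% by arm, ...), so a default run produces
realistic-looking tables without claiming replication.

:func:`planted_truth` returns the quantities the pipeline should recover —
true medians (closed form, or deterministic quadrature for convolutions)
and expected covariate prevalences — enabling parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml
from scipy import optimize, stats

from .claims import DiagnosisEvent, DispensingEvent, PatientBundle
from .codesets import CodeRuleSet, load_code_rules
from .cohort import DATA_CUTOFF, STUDY_INDEX_END, STUDY_INDEX_START
from .survival import DAYS_PER_MONTH

__all__ = [
    "DistributionSpec",
    "SimulationConfig",
    "PlantedTruth",
    "SyntheticClaims",
    "default_config",
    "generate",
    "planted_truth",
]

ARMS = ("AI", "FULV")

_CDK_AGENTS = ["palbociclib", "ribociclib", "abemaciclib"]
_CDK_WEIGHTS = [0.60, 0.25, 0.15]
_AI_AGENTS = ["letrozole", "anastrozole", "exemestane"]
_AI_WEIGHTS = [0.55, 0.30, 0.15]
_ET_MONO_AGENTS = ["letrozole", "tamoxifen", "fulvestrant", "exemestane"]

_NEXT_CATEGORIES = ("chemotherapy-based", "CDK4/6-based", "ET-based")


@dataclass(frozen=True)
class DistributionSpec:
    """Positive duration distribution in months.

    Families: ``exponential`` (``rate`` per month or ``median``), ``weibull``
    (``shape``, ``scale``), ``lognormal`` (``sigma`` plus ``mu`` or
    ``median``; ``sigma=0`` degenerates to a point mass).
    """

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        fam = self.family
        p = self.params
        if fam == "exponential":
            if ("rate" in p) == ("median" in p):
                raise ValueError("exponential needs exactly one of rate/median")
            if next(iter(p.values())) <= 0:
                raise ValueError("exponential parameter must be positive")
        elif fam == "weibull":
            if p.get("shape", 0) <= 0 or p.get("scale", 0) <= 0:
                raise ValueError("weibull needs positive shape and scale")
        elif fam == "lognormal":
            if ("mu" in p) == ("median" in p):
                raise ValueError("lognormal needs exactly one of mu/median")
            if p.get("sigma", -1) < 0:
                raise ValueError("lognormal needs sigma >= 0")
        else:
            raise ValueError(f"unsupported distribution family {fam!r}")

    @property
    def _mu(self) -> float:
        return self.params["mu"] if "mu" in self.params else math.log(self.params["median"])

    @property
    def _rate(self) -> float:
        if "rate" in self.params:
            return self.params["rate"]
        return math.log(2) / self.params["median"]

    def median(self) -> float:
        """Closed-form median in months."""
        if self.family == "exponential":
            return math.log(2) / self._rate
        if self.family == "weibull":
            return self.params["scale"] * math.log(2) ** (1.0 / self.params["shape"])
        return math.exp(self._mu)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "exponential":
            return rng.exponential(1.0 / self._rate, size)
        if self.family == "weibull":
            return self.params["scale"] * rng.weibull(self.params["shape"], size)
        sigma = self.params["sigma"]
        if sigma == 0:
            draw = np.full(size if size is not None else (), math.exp(self._mu))
            return float(draw) if size is None else draw
        return rng.lognormal(self._mu, sigma, size)

    def sf(self, t: float) -> float:
        """Survival function S(t)."""
        if t <= 0:
            return 1.0
        if self.family == "exponential":
            return math.exp(-self._rate * t)
        if self.family == "weibull":
            return math.exp(-((t / self.params["scale"]) ** self.params["shape"]))
        sigma = self.params["sigma"]
        if sigma == 0:
            return 1.0 if t < math.exp(self._mu) else 0.0
        return float(stats.lognorm.sf(t, s=sigma, scale=math.exp(self._mu)))


def _ln(median: float, sigma: float) -> DistributionSpec:
    return DistributionSpec("lognormal", {"median": median, "sigma": sigma})


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable generator parameters; the defaults are the study conditions.

    Durations are months, gaps and refill quantities are days, hazards are
    per month.  Per-arm values are keyed ``"AI"`` / ``"FULV"`` by the
    endocrine partner of the first-line regimen.
    """

    n_patients: int = 1000
    seed: int = 0
    arm_mix: Mapping[str, float] = field(
        default_factory=lambda: {"AI": 0.67, "FULV": 0.33}
    )
    line1_duration: Mapping[str, DistributionSpec] = field(
        default_factory=lambda: {"AI": _ln(17.3, 0.9), "FULV": _ln(9.7, 0.9)}
    )
    line2_duration: DistributionSpec = field(default_factory=lambda: _ln(4.6, 0.8))
    line3_duration: DistributionSpec = field(default_factory=lambda: _ln(3.2, 0.8))
    p_next_line: Mapping[str, float] = field(
        default_factory=lambda: {"AI": 0.60, "FULV": 0.75}
    )
    next_regimen_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "AI": {"chemotherapy-based": 0.506, "CDK4/6-based": 0.231, "ET-based": 0.263},
            "FULV": {"chemotherapy-based": 0.671, "CDK4/6-based": 0.178, "ET-based": 0.151},
        }
    )
    gap_between_lines_days: tuple[int, int] = (75, 150)
    death_hazard: Mapping[str, float] = field(
        default_factory=lambda: {"AI": 0.009, "FULV": 0.019}
    )
    p_prior_ai: Mapping[str, float] = field(
        default_factory=lambda: {"AI": 0.296, "FULV": 0.723}
    )
    p_prior_tamoxifen: Mapping[str, float] = field(
        default_factory=lambda: {"AI": 0.115, "FULV": 0.111}
    )
    p_prior_chemo: Mapping[str, float] = field(
        default_factory=lambda: {"AI": 0.067, "FULV": 0.138}
    )
    p_prior_radiotherapy: Mapping[str, float] = field(
        default_factory=lambda: {"AI": 0.020, "FULV": 0.033}
    )
    p_prior_surgery: Mapping[str, float] = field(
        default_factory=lambda: {"AI": 0.082, "FULV": 0.038}
    )
    p_visceral: Mapping[str, float] = field(
        default_factory=lambda: {"AI": 0.179, "FULV": 0.096}
    )
    p_bone_mets: float = 0.40
    comorbidity_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {
            "myocardial_infarction": 0.03,
            "congestive_heart_failure": 0.06,
            "cerebrovascular_disease": 0.05,
            "dementia": 0.03,
            "chronic_pulmonary_disease": 0.09,
            "rheumatic_disease": 0.03,
            "diabetes_uncomplicated": 0.10,
            "diabetes_complicated": 0.05,
            "renal_disease": 0.07,
            "moderate_severe_liver_disease": 0.02,
            "hemiplegia_paraplegia": 0.01,
        }
    )
    age_mean: float = 66.5
    age_sd: float = 12.0
    age_range: tuple[float, float] = (25.0, 100.0)
    p_female: float = 0.993
    dispensing_interval: int = 30
    adherence_jitter: int = 7
    mbc_diagnosis_window: tuple[dt.date, dt.date] = (STUDY_INDEX_START, STUDY_INDEX_END)
    cutoff: dt.date = DATA_CUTOFF
    p_trial: float = 0.002
    p_prior_primary: float = 0.004
    p_ai_agent_swap: float = 0.15

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.dispensing_interval < 1:
            raise ValueError("dispensing_interval must be >= 1")
        if self.adherence_jitter < 0:
            raise ValueError("adherence_jitter must be >= 0")
        if self.adherence_jitter >= self.dispensing_interval:
            raise ValueError("adherence_jitter must be below the refill interval")
        if abs(sum(self.arm_mix.values()) - 1.0) > 1e-9:
            raise ValueError("arm_mix must sum to 1")
        probs = [
            *self.arm_mix.values(),
            *self.p_next_line.values(),
            *self.p_prior_ai.values(),
            *self.p_prior_tamoxifen.values(),
            *self.p_prior_chemo.values(),
            *self.p_prior_radiotherapy.values(),
            *self.p_prior_surgery.values(),
            *self.p_visceral.values(),
            self.p_bone_mets,
            self.p_female,
            self.p_trial,
            self.p_prior_primary,
            self.p_ai_agent_swap,
            *self.comorbidity_prevalences.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for arm in ARMS:
            if arm not in self.arm_mix or arm not in self.line1_duration:
                raise ValueError(f"missing arm {arm!r} in arm-specific parameters")
            cat = self.next_regimen_probs[arm]
            if abs(sum(cat.values()) - 1.0) > 1e-9:
                raise ValueError(f"next_regimen_probs[{arm}] must sum to 1")
            if any(h < 0 for h in self.death_hazard.values()):
                raise ValueError("death hazards must be >= 0")
        lo, hi = self.gap_between_lines_days
        if lo > hi or lo < 1:
            raise ValueError("gap_between_lines_days must be a valid positive range")
        if self.mbc_diagnosis_window[0] > self.mbc_diagnosis_window[1]:
            raise ValueError("mbc_diagnosis_window start after end")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        kwargs = dict(raw)
        for key in ("line2_duration", "line3_duration"):
            if key in kwargs and isinstance(kwargs[key], Mapping):
                kwargs[key] = DistributionSpec(**kwargs[key])
        if "line1_duration" in kwargs:
            kwargs["line1_duration"] = {
                arm: spec if isinstance(spec, DistributionSpec) else DistributionSpec(**spec)
                for arm, spec in kwargs["line1_duration"].items()
            }
        for key in ("mbc_diagnosis_window",):
            if key in kwargs:
                kwargs[key] = tuple(
                    d if isinstance(d, dt.date) else dt.date.fromisoformat(d)
                    for d in kwargs[key]
                )
        if "cutoff" in kwargs and not isinstance(kwargs["cutoff"], dt.date):
            kwargs["cutoff"] = dt.date.fromisoformat(kwargs["cutoff"])
        for key in ("gap_between_lines_days", "age_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_config(n_patients: int = 1000, seed: int = 0) -> SimulationConfig:
    return SimulationConfig(n_patients=n_patients, seed=seed)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth quantities the pipeline should recover on synthetic data.

    ``median_line1_tttd_months`` is the median of min(line-1 duration, death
    time) — the estimand of the TTTD Kaplan–Meier fit under independent
    administrative censoring.  ``median_line1_ttnt_months`` is the median of
    the latent next-line start-time law (duration + between-line gap, with
    mass ``1 − p_next_line`` at infinity); ``None`` when that law never
    reaches 0.5.
    """

    arm_shares: Mapping[str, float]
    median_line1_duration_months: Mapping[str, float]
    median_line1_tttd_months: Mapping[str, float]
    median_line1_ttnt_months: Mapping[str, float | None]
    expected_prevalences: Mapping[str, Mapping[str, float]]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def planted_truth(config: SimulationConfig) -> PlantedTruth:
    """Derive the generator's ground truth analytically (no simulation)."""
    config.validate()
    tttd = {}
    ttnt = {}
    for arm in ARMS:
        dist = config.line1_duration[arm]
        hazard = config.death_hazard[arm]
        tttd[arm] = _median_min_with_exponential(dist, hazard)
        ttnt[arm] = _median_latent_ttnt(
            dist, config.gap_between_lines_days, config.p_next_line[arm]
        )
    prevalences = {
        arm: {
            "female": config.p_female,
            "visceral": config.p_visceral[arm],
            "endocrine_resistant": 1.0
            - (1.0 - config.p_prior_ai[arm]) * (1.0 - config.p_prior_tamoxifen[arm]),
            "lookback_ai": config.p_prior_ai[arm],
            "lookback_tamoxifen": config.p_prior_tamoxifen[arm],
            "lookback_chemo": config.p_prior_chemo[arm],
        }
        for arm in ARMS
    }
    return PlantedTruth(
        arm_shares=dict(config.arm_mix),
        median_line1_duration_months={
            arm: config.line1_duration[arm].median() for arm in ARMS
        },
        median_line1_tttd_months=tttd,
        median_line1_ttnt_months=ttnt,
        expected_prevalences=prevalences,
    )


def _median_min_with_exponential(dist: DistributionSpec, hazard: float) -> float:
    """Median of min(D, T) for D ~ dist and T ~ Exp(hazard), independent."""
    if hazard <= 0:
        return dist.median()

    def g(t: float) -> float:
        return dist.sf(t) * math.exp(-hazard * t) - 0.5

    hi = 1.0
    while g(hi) > 0 and hi < 1e6:
        hi *= 2
    return float(optimize.brentq(g, 1e-12, hi))


def _median_latent_ttnt(
    dist: DistributionSpec, gap_days: tuple[int, int], p_next: float
) -> float | None:
    """Median of the latent TTNT law: p_next * P(D + G <= t) crossing 0.5.

    The uniform between-line gap G is integrated by fixed quadrature, so the
    result is deterministic.
    """
    if p_next <= 0.5:
        return None
    gaps = np.linspace(gap_days[0], gap_days[1], 257) / DAYS_PER_MONTH

    def cdf(t: float) -> float:
        return float(np.mean([1.0 - dist.sf(t - g) for g in gaps]))

    def g(t: float) -> float:
        return p_next * cdf(t) - 0.5

    hi = 1.0
    while g(hi) < 0 and hi < 1e6:
        hi *= 2
    return float(optimize.brentq(g, 1e-12, hi))


@dataclass(frozen=True)
class SyntheticClaims:
    """Generator output: patient bundles plus dated procedure markers."""

    bundles: tuple[PatientBundle, ...]
    procedures: Mapping[str, tuple[tuple[dt.date, str], ...]]


def generate(config: SimulationConfig, rules: CodeRuleSet | None = None) -> SyntheticClaims:
    """Draw a full synthetic claims set; identical config ⇒ identical output."""
    config.validate()
    rules = rules or load_code_rules()
    rng = np.random.default_rng(config.seed)

    comorb_codes = {
        cond.condition: cond.code_prefixes[0] for cond in rules.charlson
    }
    visceral_codes = sorted(rules.visceral_codes)
    window_start, window_end = config.mbc_diagnosis_window
    window_days = (window_end - window_start).days
    cutoff = config.cutoff

    bundles: list[PatientBundle] = []
    procedures: dict[str, tuple[tuple[dt.date, str], ...]] = {}

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        sex = "F" if rng.random() < config.p_female else "M"
        arm = "AI" if rng.random() < config.arm_mix["AI"] else "FULV"
        index = window_start + dt.timedelta(days=int(rng.integers(0, window_days + 1)))

        age = float(rng.normal(config.age_mean, config.age_sd))
        lo, hi = config.age_range
        for _ in range(100):
            if lo <= age <= hi:
                break
            age = float(rng.normal(config.age_mean, config.age_sd))
        age = min(max(age, lo), hi)
        birth = index - dt.timedelta(days=int(round(age * 365.25)))

        hazard = config.death_hazard[arm]
        if hazard > 0:
            death_months = float(rng.exponential(1.0 / hazard))
            death = index + dt.timedelta(days=int(round(death_months * DAYS_PER_MONTH)))
            death_date = death if death <= cutoff else None
        else:
            death_date = None
        horizon = min(cutoff, death_date) if death_date else cutoff

        diagnoses: list[DiagnosisEvent] = []
        dispensings: list[DispensingEvent] = []

        def add_dx(code: str, date: dt.date) -> None:
            if date <= horizon:
                diagnoses.append(DiagnosisEvent(pid, date, code))

        def add_rx(drug: str, date: dt.date, supply: int) -> None:
            if date <= horizon and supply >= 1:
                dispensings.append(DispensingEvent(pid, date, drug, supply))

        # breast-cancer context + metastasis coding at index
        add_dx("C509", index - dt.timedelta(days=int(rng.integers(400, 1001))))
        if rng.random() < config.p_visceral[arm]:
            add_dx(str(rng.choice(visceral_codes)), index)
        if rng.random() < config.p_bone_mets:
            add_dx("C795", index)
        if rng.random() < config.p_prior_primary:
            add_dx("C341", index - dt.timedelta(days=int(rng.integers(100, 901))))
        for cond in sorted(config.comorbidity_prevalences):
            if rng.random() < config.comorbidity_prevalences[cond]:
                add_dx(
                    comorb_codes[cond],
                    index - dt.timedelta(days=int(rng.integers(30, 1091))),
                )

        # lookback treatment history (offsets keep prior exposure clear of
        # the first-line grace window: >= 100 days before index)
        if rng.random() < config.p_prior_ai[arm]:
            drug = str(rng.choice(_AI_AGENTS, p=_AI_WEIGHTS))
            add_rx(drug, index - dt.timedelta(days=int(rng.integers(100, 351))), 30)
        if rng.random() < config.p_prior_tamoxifen[arm]:
            add_rx("tamoxifen", index - dt.timedelta(days=int(rng.integers(100, 351))), 30)
        if rng.random() < config.p_prior_chemo[arm]:
            add_rx("chemotherapy", index - dt.timedelta(days=int(rng.integers(100, 351))), 30)
        procs = []
        if rng.random() < config.p_prior_radiotherapy[arm]:
            procs.append(
                (index - dt.timedelta(days=int(rng.integers(30, 351))), "radiotherapy")
            )
        if rng.random() < config.p_prior_surgery[arm]:
            procs.append(
                (index - dt.timedelta(days=int(rng.integers(30, 351))), "surgery")
            )
        if procs:
            procedures[pid] = tuple(procs)

        # treatment-line schedule in days relative to index
        plans: list[tuple[int, int, list[str]]] = []  # (start_day, end_day, drugs)
        cdk = str(rng.choice(_CDK_AGENTS, p=_CDK_WEIGHTS))
        if arm == "AI":
            partner = str(rng.choice(_AI_AGENTS, p=_AI_WEIGHTS))
        else:
            partner = "fulvestrant"
        d1 = max(1, int(round(float(config.line1_duration[arm].sample(rng)) * DAYS_PER_MONTH)))
        plans.append((0, d1, [cdk, partner]))

        cur_end = d1
        for line_no, dist in ((2, config.line2_duration), (3, config.line3_duration)):
            if rng.random() >= config.p_next_line[arm]:
                break
            gap = int(rng.integers(config.gap_between_lines_days[0],
                                   config.gap_between_lines_days[1] + 1))
            start = cur_end + gap
            dur = max(1, int(round(float(dist.sample(rng)) * DAYS_PER_MONTH)))
            cat_probs = config.next_regimen_probs[arm]
            cat = str(rng.choice(_NEXT_CATEGORIES, p=[cat_probs[c] for c in _NEXT_CATEGORIES]))
            if cat == "chemotherapy-based":
                drugs = ["chemotherapy"]
            elif cat == "CDK4/6-based":
                re_partner = "fulvestrant" if rng.random() < 0.5 else str(
                    rng.choice(_AI_AGENTS, p=_AI_WEIGHTS)
                )
                drugs = [str(rng.choice(_CDK_AGENTS, p=_CDK_WEIGHTS)), re_partner]
            else:
                drugs = [str(rng.choice(_ET_MONO_AGENTS))]
            plans.append((start, start + dur, drugs))
            cur_end = start + dur

        # AI-agent swap mid-line (exchangeable: must not advance the line)
        swap_line1_at: int | None = None
        if arm == "AI" and config.p_ai_agent_swap > 0 and rng.random() < config.p_ai_agent_swap:
            if d1 > 3 * config.dispensing_interval:
                swap_line1_at = d1 // 2

        interval = config.dispensing_interval
        jit = config.adherence_jitter
        for start, end, drugs in plans:
            for drug in drugs:
                s = start
                current = drug
                first = True
                while s < end:
                    # the final fill is truncated to the planned stop date and
                    # never jittered, so coverage ends exactly at `end - 1`
                    final = s + interval >= end
                    j = int(rng.integers(-jit, jit + 1)) if jit and not (first or final) else 0
                    day = s + j
                    supply = min(interval, end - day)
                    if (
                        start == 0
                        and swap_line1_at is not None
                        and current in _AI_AGENTS
                        and day >= swap_line1_at
                    ):
                        current = next(a for a in _AI_AGENTS if a != drug)
                    add_rx(current, index + dt.timedelta(days=day), supply)
                    s += interval
                    first = False

        bundles.append(
            PatientBundle(
                patient_id=pid,
                sex=sex,
                birth_date=birth,
                death_date=death_date,
                last_record_date=horizon,
                trial_flag=bool(rng.random() < config.p_trial),
                dispensings=tuple(dispensings),
                diagnoses=tuple(diagnoses),
            )
        )

    return SyntheticClaims(bundles=tuple(bundles), procedures=procedures)
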