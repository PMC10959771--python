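"""Cohort phenotyping: index date, mBC ascertainment, eligibility, baseline.

The cohort of interest is adults newly treated for hormone-receptor-positive
HER2-negative metastatic breast cancer (mBC) who start a CDK4/6 inhibitor
combined with an aromatase inhibitor or with fulvestrant as first line.
Because claims carry no tumour registry, mBC status is *phenotyped* from
coded events:

* the **index date** is the first occurrence of an mBC-defining drug
  (fulvestrant, everolimus, or a CDK4/6 inhibitor) or of a
  secondary-malignancy diagnosis code (C77*/C78*/C79*, excluding C77.3 and
  C79.2);
* the **ascertainment algorithm** requires an mBC-defining drug, or a
  secondary-malignancy diagnosis followed (same day allowed) by tamoxifen or
  an AI — and, in either case, no HER2-targeted therapy ever;
* eligibility restricts to adults indexed between 2014-01-01 and 2019-06-30
  whose first line contains a CDK4/6 inhibitor plus exactly one endocrine
  partner, without another primary malignancy in the 3-year lookback, trial
  participation, or invalid data.

Baseline covariates (visceral disease, Charlson category, one-year treatment
history, the endocrine-sensitivity proxy, the age-based menopause proxy) are
derived from the lookback window around the index date.
"""

from __future__ import annotations

import datetime as dt
from collections import OrderedDict
from dataclasses import dataclass
from enum import Enum
from math import floor
from typing import Iterable, Mapping, Sequence

from .claims import PatientBundle
from .codesets import CodeRuleSet, DrugClass
from .lines import (
    DEFAULT_COMBO_WINDOW_DAYS,
    DEFAULT_GRACE_DAYS,
    LineOfTherapy,
    build_exposure_intervals,
    derive_lines,
)

__all__ = [
    "STUDY_INDEX_START",
    "STUDY_INDEX_END",
    "DATA_CUTOFF",
    "CohortRecord",
    "RejectionReason",
    "find_index_date",
    "meets_mbc_algorithm",
    "apply_eligibility",
    "derive_baseline",
    "build_cohort",
]

STUDY_INDEX_START = dt.date(2014, 1, 1)
STUDY_INDEX_END = dt.date(2019, 6, 30)
DATA_CUTOFF = dt.date(2019, 12, 31)

LOOKBACK_DAYS = 3 * 365
HISTORY_WINDOW_DAYS = 365

_INDEX_TRIGGER_CLASSES = {
    DrugClass.FULVESTRANT,
    DrugClass.EVEROLIMUS,
    DrugClass.CDK46I,
}
_ET_AFTER_METS_CLASSES = {DrugClass.TAMOXIFEN, DrugClass.AI}


class RejectionReason(str, Enum):
    """Enumerated attrition steps, in application order."""

    NO_INDEX = "no_index_event"
    NOT_MBC = "mbc_algorithm_not_met"
    OUTSIDE_ERA = "index_outside_study_era"
    UNDER_AGE = "age_under_18"
    PRIOR_PRIMARY = "prior_primary_malignancy"
    TRIAL = "clinical_trial_participation"
    LINE1_INELIGIBLE = "first_line_not_cdk46i_plus_single_et"
    INVALID = "missing_or_invalid_data"


@dataclass(frozen=True)
class CohortRecord:
    patient_id: str
    index_date: dt.date
    first_mbc_evidence_date: dt.date
    age_at_index: float
    sex: str
    menopausal_status: str  # pre | post | not_applicable
    arm: str  # CDK46I_AI | CDK46I_FULV
    endocrine_status: str  # sensitive | resistant
    visceral: bool
    charlson_score: int
    charlson_category: str
    lookback_any_cancer_med: bool
    lookback_ai: bool
    lookback_tamoxifen: bool
    lookback_chemo: bool
    lookback_radiotherapy: bool
    lookback_surgery: bool
    followup_end: dt.date
    death_observed: bool
    index_year: int


def find_index_date(bundle: PatientBundle, rules: CodeRuleSet) -> dt.date | None:
    """Earliest mBC-defining drug dispensing or secondary-malignancy diagnosis."""
    candidates = [
        ev.date
        for ev in bundle.dispensings
        if rules.classify_drug(ev.drug) in _INDEX_TRIGGER_CLASSES
    ]
    candidates += [
        ev.date for ev in bundle.diagnoses if rules.is_secondary_malignancy(ev.icd10)
    ]
    return min(candidates) if candidates else None


def meets_mbc_algorithm(bundle: PatientBundle, rules: CodeRuleSet) -> bool:
    """Claims-based mBC ascertainment.

    True iff the patient has an mBC-defining drug dispensing (CDK4/6
    inhibitor, fulvestrant or everolimus), or a secondary-malignancy
    diagnosis followed on the same or a later day by tamoxifen or an AI —
    and never a HER2-targeted dispensing (which marks a HER2+ subtype).
    """
    classes = [(ev.date, rules.classify_drug(ev.drug)) for ev in bundle.dispensings]
    if any(cls is DrugClass.HER2_TARGETED for _, cls in classes):
        return False
    if any(cls in _INDEX_TRIGGER_CLASSES for _, cls in classes):
        return True
    mets_dates = [
        ev.date for ev in bundle.diagnoses if rules.is_secondary_malignancy(ev.icd10)
    ]
    if not mets_dates:
        return False
    first_mets = min(mets_dates)
    return any(
        cls in _ET_AFTER_METS_CLASSES and date >= first_mets for date, cls in classes
    )


def _age_years(birth: dt.date, at: dt.date) -> float:
    return floor((at - birth).days / 365.25 * 10) / 10


def derive_baseline(
    bundle: PatientBundle,
    index_date: dt.date,
    first_mbc_evidence_date: dt.date,
    rules: CodeRuleSet,
    procedures: Sequence[tuple[dt.date, str]] = (),
) -> dict:
    """Baseline covariates from the lookback windows.

    Visceral disease is any configured visceral-metastasis code on/before
    the index date; Charlson uses diagnoses in the 3 years up to index
    (cancer codes never score); treatment-history flags cover the 365 days
    strictly before index; the endocrine-sensitivity proxy looks at the 365
    days strictly before the first mBC evidence.  ``procedures`` are
    optional dated radiotherapy/surgery markers.
    """
    visceral = any(
        ev.date <= index_date and rules.is_visceral(ev.icd10)
        for ev in bundle.diagnoses
    )

    charlson_lo = index_date - dt.timedelta(days=LOOKBACK_DAYS)
    charlson_codes = {
        ev.icd10 for ev in bundle.diagnoses if charlson_lo <= ev.date <= index_date
    }
    score = rules.charlson_score(charlson_codes)

    hist_lo = index_date - dt.timedelta(days=HISTORY_WINDOW_DAYS)
    hist_classes = {
        rules.classify_drug(ev.drug)
        for ev in bundle.dispensings
        if hist_lo <= ev.date < index_date
    }
    hist_classes.discard(DrugClass.NONE)

    endo_lo = first_mbc_evidence_date - dt.timedelta(days=HISTORY_WINDOW_DAYS)
    resistant = any(
        rules.classify_drug(ev.drug) in (DrugClass.AI, DrugClass.TAMOXIFEN)
        for ev in bundle.dispensings
        if endo_lo <= ev.date < first_mbc_evidence_date
    )

    proc_kinds = {
        kind for date, kind in procedures if hist_lo <= date < index_date
    }

    age = _age_years(bundle.birth_date, index_date)
    if bundle.sex == "M":
        menopause = "not_applicable"
    else:
        menopause = "post" if age >= 50 else "pre"

    return {
        "age_at_index": age,
        "menopausal_status": menopause,
        "visceral": visceral,
        "charlson_score": score,
        "charlson_category": rules.charlson_category(score),
        "endocrine_status": "resistant" if resistant else "sensitive",
        "lookback_any_cancer_med": bool(hist_classes),
        "lookback_ai": DrugClass.AI in hist_classes,
        "lookback_tamoxifen": DrugClass.TAMOXIFEN in hist_classes,
        "lookback_chemo": DrugClass.CHEMO in hist_classes,
        "lookback_radiotherapy": "radiotherapy" in proc_kinds,
        "lookback_surgery": "surgery" in proc_kinds,
    }


def _prior_primary(bundle: PatientBundle, index_date: dt.date, rules: CodeRuleSet) -> bool:
    """Non-breast primary malignancy (C00–C97 minus C50* and all secondary
    C77–C79 codes) in the 3-year lookback up to index."""
    lo = index_date - dt.timedelta(days=LOOKBACK_DAYS)
    for ev in bundle.diagnoses:
        if not (lo <= ev.date <= index_date):
            continue
        code = ev.icd10.upper().replace(".", "")
        if not code.startswith("C"):
            continue
        try:
            block = int(code[1:3])
        except ValueError:
            continue
        if block > 97 or code.startswith("C50"):
            continue
        if code.startswith(("C77", "C78", "C79")):
            continue
        return True
    return False


def apply_eligibility(
    bundle: PatientBundle,
    index_date: dt.date | None,
    lines: Sequence[LineOfTherapy],
    rules: CodeRuleSet,
    procedures: Sequence[tuple[dt.date, str]] = (),
    cutoff: dt.date = DATA_CUTOFF,
) -> tuple[CohortRecord | None, RejectionReason | None]:
    """Run the eligibility cascade; return a record or the rejection reason.

    The first failing step determines the reason, so attrition counts over a
    population partition it exactly.
    """
    if index_date is None:
        return None, RejectionReason.NO_INDEX
    if not meets_mbc_algorithm(bundle, rules):
        return None, RejectionReason.NOT_MBC
    if not (STUDY_INDEX_START <= index_date <= STUDY_INDEX_END):
        return None, RejectionReason.OUTSIDE_ERA
    baseline = derive_baseline(bundle, index_date, index_date, rules, procedures)
    if baseline["age_at_index"] < 18:
        return None, RejectionReason.UNDER_AGE
    if _prior_primary(bundle, index_date, rules):
        return None, RejectionReason.PRIOR_PRIMARY
    if bundle.trial_flag:
        return None, RejectionReason.TRIAL
    if not lines:
        return None, RejectionReason.LINE1_INELIGIBLE
    line1 = lines[0]
    partners = line1.drug_classes & {DrugClass.AI, DrugClass.FULVESTRANT}
    if DrugClass.CDK46I not in line1.drug_classes or len(partners) != 1:
        return None, RejectionReason.LINE1_INELIGIBLE
    arm = "CDK46I_AI" if DrugClass.AI in partners else "CDK46I_FULV"

    followup_end = min(bundle.last_record_date, cutoff)
    death_observed = bundle.death_date is not None and bundle.death_date <= cutoff
    if death_observed:
        followup_end = min(followup_end, bundle.death_date)

    record = CohortRecord(
        patient_id=bundle.patient_id,
        index_date=index_date,
        first_mbc_evidence_date=index_date,
        sex=bundle.sex,
        arm=arm,
        followup_end=followup_end,
        death_observed=death_observed,
        index_year=index_date.year,
        **baseline,
    )
    return record, None


def build_cohort(
    bundles: Iterable[PatientBundle],
    rules: CodeRuleSet,
    procedures: Mapping[str, Sequence[tuple[dt.date, str]]] | None = None,
    grace_days: int = DEFAULT_GRACE_DAYS,
    combo_window_days: int = DEFAULT_COMBO_WINDOW_DAYS,
    cutoff: dt.date = DATA_CUTOFF,
) -> tuple[list[CohortRecord], dict[str, list[LineOfTherapy]], "OrderedDict[str, int]"]:
    """Phenotype a population end to end.

    Returns included cohort records, the derived lines for included
    patients, and an ordered attrition table whose counts (including
    ``included``) sum to the number of input bundles.
    """
    procedures = procedures or {}
    attrition: OrderedDict[str, int] = OrderedDict(
        (reason.value, 0) for reason in RejectionReason
    )
    attrition["included"] = 0

    records: list[CohortRecord] = []
    lines_by_patient: dict[str, list[LineOfTherapy]] = {}
    for bundle in bundles:
        if bundle.validate():
            attrition[RejectionReason.INVALID.value] += 1
            continue
        index_date = find_index_date(bundle, rules)
        lines: list[LineOfTherapy] = []
        if index_date is not None:
            intervals = build_exposure_intervals(
                bundle.dispensings, rules, grace_days=grace_days
            )
            lines = derive_lines(
                intervals,
                index_date,
                bundle.death_date,
                cutoff,
                patient_id=bundle.patient_id,
                grace_days=grace_days,
                combo_window_days=combo_window_days,
            )
        record, reason = apply_eligibility(
            bundle,
            index_date,
            lines,
            rules,
            procedures=procedures.get(bundle.patient_id, ()),
            cutoff=cutoff,
        )
        if record is None:
            attrition[reason.value] += 1
        else:
            records.append(record)
            lines_by_patient[bundle.patient_id] = lines
            attrition["included"] += 1
    return records, lines_by_patient, attrition
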