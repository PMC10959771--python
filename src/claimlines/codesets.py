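"""Drug-class and ICD-10 code classification rules.

Every other module classifies coded claims events through this one: drug
identifiers (substance names or ATC codes) map to treatment classes, ICD-10
codes are screened for secondary-malignancy / visceral-metastasis status, and
diagnosis histories are scored with the Charlson comorbidity index (cancer
categories excluded, since the index disease of the cohort is cancer).

Rules live in a human-editable YAML file; :func:`load_code_rules` with no
argument loads the packaged default.  Classification is deterministic and
total: every drug string maps to exactly one :class:`DrugClass`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "DrugClass",
    "CodeRuleSet",
    "load_code_rules",
    "normalize_icd10",
    "CodeValidationError",
]


class CodeValidationError(ValueError):
    """Raised for malformed drug identifiers or ICD-10 codes."""


class DrugClass(str, Enum):
    """Treatment classes used for regimen and line-of-therapy construction."""

    CDK46I = "CDK46I"
    AI = "AI"
    FULVESTRANT = "FULVESTRANT"
    TAMOXIFEN = "TAMOXIFEN"
    EVEROLIMUS = "EVEROLIMUS"
    HER2_TARGETED = "HER2_TARGETED"
    CHEMO = "CHEMO"
    OTHER_ANTICANCER = "OTHER_ANTICANCER"
    NONE = "NONE"


#: Classes eligible to open or join a treatment line.  HER2-targeted therapy
#: is an upstream cohort exclusion, never a line component.
LINE_ELIGIBLE_CLASSES = frozenset(
    {
        DrugClass.CDK46I,
        DrugClass.AI,
        DrugClass.FULVESTRANT,
        DrugClass.TAMOXIFEN,
        DrugClass.EVEROLIMUS,
        DrugClass.CHEMO,
        DrugClass.OTHER_ANTICANCER,
    }
)

#: Endocrine-therapy classes (used for regimen-category summaries).
ET_CLASSES = frozenset(
    {DrugClass.AI, DrugClass.FULVESTRANT, DrugClass.TAMOXIFEN, DrugClass.EVEROLIMUS}
)

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,4}$")
_ATC_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z]{0,2}[0-9]{0,2}$")

CHARLSON_CATEGORIES = ("0", "1-2", "3-4", ">=5")


def normalize_icd10(code: str) -> str:
    """Return the undotted upper-case form of an ICD-10 code.

    ``"c78.0"`` and ``"C780"`` normalize identically; malformed codes raise
    :class:`CodeValidationError`.
    """
    if not isinstance(code, str) or not code.strip():
        raise CodeValidationError(f"empty or non-string ICD-10 code: {code!r}")
    norm = code.strip().upper().replace(".", "")
    if not _ICD10_RE.match(norm):
        raise CodeValidationError(f"malformed ICD-10 code: {code!r}")
    return norm


@dataclass(frozen=True)
class CharlsonCondition:
    condition: str
    weight: int
    code_prefixes: tuple[str, ...]

    def matches(self, normalized_codes: Iterable[str]) -> bool:
        return any(
            c.startswith(p) for c in normalized_codes for p in self.code_prefixes
        )


@dataclass(frozen=True)
class CodeRuleSet:
    """Immutable bundle of classification rules loaded from one config file.

    Attributes
    ----------
    drug_map
        Lower-cased drug identifier (name or ATC code) -> :class:`DrugClass`.
    chemo_atc_prefixes
        ATC prefixes whose unmapped members default to ``CHEMO``.
    secondary_malignancy_prefixes / secondary_malignancy_exclusions
        Undotted ICD-10 prefixes / exact codes defining metastatic-disease
        diagnoses.
    visceral_codes
        Undotted ICD-10 codes counted as visceral metastases.
    charlson
        Charlson conditions with code prefixes and integer weights.
    charlson_hierarchy
        (severe, mild) pairs where the severe condition supersedes the mild.
    """

    version: str
    drug_map: Mapping[str, DrugClass]
    chemo_atc_prefixes: tuple[str, ...]
    secondary_malignancy_prefixes: tuple[str, ...]
    secondary_malignancy_exclusions: frozenset[str]
    visceral_codes: frozenset[str]
    charlson: tuple[CharlsonCondition, ...]
    charlson_hierarchy: tuple[tuple[str, str], ...] = field(default=())

    # -- drug classification -------------------------------------------------

    def classify_drug(self, identifier: str) -> DrugClass:
        """Map a drug name or ATC code to its unique treatment class.

        Case-insensitive.  Unknown identifiers return ``DrugClass.NONE``;
        unmapped ATC codes under a configured chemotherapy prefix (default
        L01, antineoplastic agents) return ``CHEMO``.
        """
        if not isinstance(identifier, str) or not identifier.strip():
            raise CodeValidationError(f"empty drug identifier: {identifier!r}")
        key = identifier.strip().lower()
        if key in self.drug_map:
            return self.drug_map[key]
        token = identifier.strip().upper()
        if _ATC_RE.match(token):
            for prefix in self.chemo_atc_prefixes:
                if token.startswith(prefix):
                    return DrugClass.CHEMO
        return DrugClass.NONE

    # -- ICD-10 screens ------------------------------------------------------

    def is_secondary_malignancy(self, icd10: str) -> bool:
        """True iff the code denotes a secondary malignant neoplasm.

        A code qualifies when it starts with a configured prefix (C77/C78/C79
        by default) and is not an exact exclusion (C77.3 regional-node and
        C79.2 skin metastases by default).  Dotted and undotted forms are
        equivalent.
        """
        norm = normalize_icd10(icd10)
        if norm in self.secondary_malignancy_exclusions:
            return False
        return any(norm.startswith(p) for p in self.secondary_malignancy_prefixes)

    def is_visceral(self, icd10: str) -> bool:
        """True iff the code denotes a visceral metastasis site.

        Default sites: liver, lung, pleura, peritoneum, adrenal gland, ovary,
        brain.  Bone and skin metastases are not visceral.
        """
        return normalize_icd10(icd10) in self.visceral_codes

    # -- Charlson ------------------------------------------------------------

    def charlson_score(self, diagnosis_codes: Iterable[str]) -> int:
        """Weighted count of distinct Charlson conditions present in codes.

        Each condition contributes its weight at most once; within a
        configured hierarchy pair (e.g. complicated vs uncomplicated
        diabetes) only the severe member counts.  Codes matching no condition
        contribute nothing, so the score is monotone under adding codes.
        """
        normalized = {normalize_icd10(c) for c in diagnosis_codes}
        matched = {c.condition for c in self.charlson if c.matches(normalized)}
        for severe, mild in self.charlson_hierarchy:
            if severe in matched:
                matched.discard(mild)
        weights = {c.condition: c.weight for c in self.charlson}
        return sum(weights[name] for name in matched)

    @staticmethod
    def charlson_category(score: int) -> str:
        """Bin a Charlson score into the reporting categories 0 / 1-2 / 3-4 / >=5."""
        if score < 0:
            raise ValueError("Charlson score cannot be negative")
        if score == 0:
            return "0"
        if score <= 2:
            return "1-2"
        if score <= 4:
            return "3-4"
        return ">=5"


def _default_config_path() -> Path:
    return Path(str(resources.files("claimlines").joinpath("data/default_codes.yaml")))


def load_code_rules(path: str | Path | None = None) -> CodeRuleSet:
    """Load a :class:`CodeRuleSet` from YAML (packaged default if no path).

    The file is schema-checked: unknown drug classes, malformed ICD-10
    entries, or non-positive Charlson weights fail the load.
    """
    cfg_path = Path(path) if path is not None else _default_config_path()
    with open(cfg_path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CodeValidationError(f"config root must be a mapping: {cfg_path}")
    for key in ("drug_classes", "secondary_malignancy", "visceral_codes", "charlson"):
        if key not in raw:
            raise CodeValidationError(f"config missing required section {key!r}")

    drug_map: dict[str, DrugClass] = {}
    for cls_name, identifiers in raw["drug_classes"].items():
        try:
            cls = DrugClass(cls_name)
        except ValueError as exc:
            raise CodeValidationError(f"unknown drug class {cls_name!r}") from exc
        for ident in identifiers:
            key = str(ident).strip().lower()
            if key in drug_map and drug_map[key] is not cls:
                raise CodeValidationError(
                    f"drug identifier {ident!r} mapped to two classes"
                )
            drug_map[key] = cls

    sm = raw["secondary_malignancy"]
    prefixes = tuple(normalize_icd10(p) for p in sm["prefixes"])
    exclusions = frozenset(normalize_icd10(c) for c in sm.get("exclusions", []))
    visceral = frozenset(normalize_icd10(c) for c in raw["visceral_codes"])

    conditions = []
    for entry in raw["charlson"]:
        weight = int(entry["weight"])
        if weight <= 0:
            raise CodeValidationError(
                f"Charlson weight must be positive: {entry['condition']}"
            )
        conditions.append(
            CharlsonCondition(
                condition=str(entry["condition"]),
                weight=weight,
                code_prefixes=tuple(normalize_icd10(c) for c in entry["codes"]),
            )
        )
    names = {c.condition for c in conditions}
    hierarchy = tuple(
        (str(a), str(b)) for a, b in raw.get("charlson_hierarchy", [])
    )
    for severe, mild in hierarchy:
        if severe not in names or mild not in names:
            raise CodeValidationError(
                f"charlson_hierarchy refers to unknown condition: {severe}/{mild}"
            )

    return CodeRuleSet(
        version=str(raw.get("version", "unversioned")),
        drug_map=drug_map,
        chemo_atc_prefixes=tuple(
            str(p).upper() for p in raw.get("chemo_atc_prefixes", [])
        ),
        secondary_malignancy_prefixes=prefixes,
        secondary_malignancy_exclusions=exclusions,
        visceral_codes=visceral,
        charlson=tuple(conditions),
        charlson_hierarchy=hierarchy,
    )
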