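"""Regimen and line-of-therapy (LOT) derivation from dispensing streams.

A *line of therapy* is an episode of anticancer treatment.  The first line
starts at the first eligible dispensing on/after the index date and comprises
every eligible drug class observed within the combination window (30 days) of
that start.  A line ends at the earliest of:

* **augmentation** — a non-exchangeable new class starts while the line's
  supply is still active; the next line begins that day and contains the
  still-active classes plus the added one;
* **switch** — the line's supply runs out and a different class starts within
  the grace period;
* **discontinuation** — the supply runs out and nothing starts within the
  grace period (confirmed by observed gap or by death);
* **death**;
* **end of data** — the administrative cutoff, or a supply gap whose grace
  window is not fully observable before the cutoff.

Aromatase inhibitors and CDK4/6 inhibitors are *exchangeable*: substitutions
within or between those two classes never advance the line — an AI→AI agent
swap, a CDK4/6i swap, or an AI starting during a CDK4/6i-containing line all
extend the current line instead of triggering a new one.

Continuous exposure per class is reconstructed from refills by merging
dispensings whose next fill starts within ``grace_days`` of the previous
coverage end; coverage of one fill is the closed interval
``[date, date + days_supply - 1]`` and stockpiling never carries over beyond
the latest coverage end.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .claims import DispensingEvent
from .codesets import CodeRuleSet, DrugClass, LINE_ELIGIBLE_CLASSES, ET_CLASSES

__all__ = [
    "ExposureInterval",
    "LineOfTherapy",
    "EndReason",
    "build_exposure_intervals",
    "derive_lines",
    "regimen_label",
    "regimen_category",
    "DEFAULT_GRACE_DAYS",
    "DEFAULT_COMBO_WINDOW_DAYS",
]

logger = logging.getLogger(__name__)

DEFAULT_GRACE_DAYS = 60
DEFAULT_COMBO_WINDOW_DAYS = 30

#: Classes whose mutual substitution does not advance the line.
EXCHANGEABLE_CLASSES = frozenset({DrugClass.AI, DrugClass.CDK46I})

_LABEL_ORDER = [
    DrugClass.CDK46I,
    DrugClass.AI,
    DrugClass.FULVESTRANT,
    DrugClass.TAMOXIFEN,
    DrugClass.EVEROLIMUS,
    DrugClass.CHEMO,
    DrugClass.OTHER_ANTICANCER,
]


class EndReason(str, Enum):
    AUGMENTATION = "augmentation"
    SWITCH = "switch"
    DISCONTINUATION = "discontinuation"
    DEATH = "death"
    END_OF_DATA = "end_of_data"


@dataclass(frozen=True)
class ExposureInterval:
    """Continuous exposure to one drug class, merged over refills."""

    drug_class: DrugClass
    start: dt.date
    end: dt.date  # last covered day, inclusive
    dispense_dates: tuple[dt.date, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} after end {self.end}")


@dataclass(frozen=True)
class LineOfTherapy:
    patient_id: str
    ordinal: int
    start: dt.date
    end: dt.date
    drug_classes: frozenset[DrugClass]
    regimen_label: str
    end_reason: EndReason

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days


def regimen_label(drug_classes: Iterable[DrugClass]) -> str:
    """Canonical '+'-joined label, CDK4/6i first, e.g. ``CDK46I+AI``."""
    classes = set(drug_classes)
    if not classes:
        raise ValueError("regimen label requires a non-empty class set")
    return "+".join(c.value for c in _LABEL_ORDER if c in classes)


def regimen_category(drug_classes: Iterable[DrugClass]) -> str:
    """Coarse category for sequence summaries.

    Any chemotherapy makes the regimen chemotherapy-based; otherwise any
    CDK4/6 inhibitor makes it CDK4/6-based; otherwise endocrine agents make
    it ET-based; anything else is 'other'.
    """
    classes = set(drug_classes)
    if DrugClass.CHEMO in classes:
        return "chemotherapy-based"
    if DrugClass.CDK46I in classes:
        return "CDK4/6-based"
    if classes & ET_CLASSES:
        return "ET-based"
    return "other"


def build_exposure_intervals(
    dispensings: Sequence[DispensingEvent],
    rules: CodeRuleSet,
    grace_days: int = DEFAULT_GRACE_DAYS,
) -> list[ExposureInterval]:
    """Merge refills into continuous per-class exposure intervals.

    Within one drug class, a dispensing extends the current interval when its
    date falls on or before the previous coverage end plus ``grace_days``;
    the interval end is the latest coverage end seen (no additive
    stockpiling).  Dispensings mapping to ``NONE`` or to a class ineligible
    for line construction are ignored.
    """
    if grace_days < 0:
        raise ValueError("grace_days must be >= 0")
    by_class: dict[DrugClass, list[DispensingEvent]] = {}
    for ev in sorted(dispensings, key=lambda e: (e.date, e.drug)):
        cls = rules.classify_drug(ev.drug)
        if cls in LINE_ELIGIBLE_CLASSES:
            by_class.setdefault(cls, []).append(ev)

    grace = dt.timedelta(days=grace_days)
    intervals: list[ExposureInterval] = []
    for cls, events in by_class.items():
        start = events[0].date
        end = events[0].coverage_end
        dates = [events[0].date]
        for ev in events[1:]:
            if ev.date <= end + grace:
                end = max(end, ev.coverage_end)
                dates.append(ev.date)
            else:
                intervals.append(ExposureInterval(cls, start, end, tuple(dates)))
                start, end, dates = ev.date, ev.coverage_end, [ev.date]
        intervals.append(ExposureInterval(cls, start, end, tuple(dates)))
    intervals.sort(key=lambda iv: (iv.start, iv.drug_class.value))
    return intervals


def _is_exchangeable_with(cls: DrugClass, line_classes: set[DrugClass]) -> bool:
    return cls in EXCHANGEABLE_CLASSES and bool(line_classes & EXCHANGEABLE_CLASSES)


def derive_lines(
    intervals: Sequence[ExposureInterval],
    index_date: dt.date,
    death_date: dt.date | None,
    cutoff: dt.date,
    patient_id: str = "",
    grace_days: int = DEFAULT_GRACE_DAYS,
    combo_window_days: int = DEFAULT_COMBO_WINDOW_DAYS,
) -> list[LineOfTherapy]:
    """Partition post-index exposure into ordered lines of therapy.

    ``intervals`` come from :func:`build_exposure_intervals` (built with the
    same ``grace_days``).  Intervals entirely before the index date are
    excluded with a warning.  Returns lines ordered by ordinal; empty when no
    eligible dispensing occurs on/after the index date.
    """
    grace = dt.timedelta(days=grace_days)
    combo = dt.timedelta(days=combo_window_days)

    pre_index = [iv for iv in intervals if iv.end < index_date]
    if pre_index:
        logger.debug(
            "%s: %d exposure interval(s) entirely before index excluded",
            patient_id,
            len(pre_index),
        )
    ivs = [iv for iv in intervals if iv.end >= index_date and iv.start <= cutoff]

    eligible_starts = sorted(
        d for iv in ivs for d in iv.dispense_dates if index_date <= d <= cutoff
    )
    if not eligible_starts:
        return []
    if death_date is not None and eligible_starts[0] > death_date:
        return []

    lines: list[LineOfTherapy] = []
    used: set[int] = set()
    line_start: dt.date | None = eligible_starts[0]
    carried: list[ExposureInterval] = []
    ordinal = 1

    while line_start is not None:
        window_end = line_start + combo
        members = list(carried)
        for iv in ivs:
            if id(iv) in used or any(id(iv) == id(m) for m in members):
                continue
            if any(line_start <= d <= window_end for d in iv.dispense_dates):
                members.append(iv)
        member_classes = {iv.drug_class for iv in members}
        active = list(members)
        for iv in active:
            used.add(id(iv))
        supply_end = max(iv.end for iv in active)

        pending = sorted(
            (iv for iv in ivs if id(iv) not in used and iv.start > line_start),
            key=lambda iv: (iv.start, iv.drug_class.value),
        )

        end: dt.date | None = None
        reason: EndReason | None = None
        next_start: dt.date | None = None
        next_carried: list[ExposureInterval] = []

        for iv in pending:
            a = iv.start
            if death_date is not None and a > death_date:
                break
            if a > cutoff:
                break
            if _is_exchangeable_with(iv.drug_class, member_classes):
                if a <= supply_end + grace:
                    # AI/CDK4/6i substitution: extends the line, no trigger
                    active.append(iv)
                    used.add(id(iv))
                    supply_end = max(supply_end, iv.end)
                    continue
                end, reason = supply_end, EndReason.DISCONTINUATION
                next_start = a
                break
            if a <= supply_end:
                end, reason = a, EndReason.AUGMENTATION
                next_start = a
                next_carried = [x for x in active if x.end >= a] + [iv]
                break
            if a <= supply_end + grace:
                end, reason = supply_end, EndReason.SWITCH
                next_start = a
                break
            end, reason = supply_end, EndReason.DISCONTINUATION
            next_start = a
            break

        if reason is None:
            # nothing follows within the observable window
            if death_date is not None and death_date <= supply_end:
                end, reason = death_date, EndReason.DEATH
            elif supply_end >= cutoff:
                end, reason = cutoff, EndReason.END_OF_DATA
            elif supply_end + grace <= cutoff or death_date is not None:
                # gap fully observed, or no refill possible after death
                end, reason = supply_end, EndReason.DISCONTINUATION
            else:
                end, reason = supply_end, EndReason.END_OF_DATA
        elif death_date is not None and death_date < end:
            # death pre-empts a later trigger; same-day triggers take precedence
            end, reason = death_date, EndReason.DEATH
            next_start, next_carried = None, []

        if end > cutoff:
            end, reason = cutoff, EndReason.END_OF_DATA
            next_start, next_carried = None, []

        lines.append(
            LineOfTherapy(
                patient_id=patient_id,
                ordinal=ordinal,
                start=line_start,
                end=end,
                drug_classes=frozenset(member_classes),
                regimen_label=regimen_label(member_classes),
                end_reason=reason,
            )
        )
        if reason == EndReason.DEATH:
            break
        line_start = next_start
        carried = next_carried
        ordinal += 1

    return lines
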