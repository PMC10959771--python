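import datetime as dt

import pytest

from claimlines import (
    DrugClass,
    EndReason,
    build_exposure_intervals,
    derive_lines,
    regimen_category,
    regimen_label,
)
from claimlines.claims import DispensingEvent

from conftest import CUTOFF, day, make_bundle, refills

FAR_CUTOFF = dt.date(2025, 12, 31)


def disp(events):
    return [DispensingEvent("P1", d, drug, s) for d, drug, s in events]


def lines_for(bundle, rules, index=None, cutoff=FAR_CUTOFF, grace=60):
    intervals = build_exposure_intervals(bundle.dispensings, rules, grace_days=grace)
    return derive_lines(
        intervals,
        index or day(0),
        bundle.death_date,
        cutoff,
        patient_id=bundle.patient_id,
        grace_days=grace,
    )


class TestExposureIntervals:
    def test_contiguous_refills_merge(self, rules):
        ivs = build_exposure_intervals(
            disp([(day(0), "palbociclib", 30), (day(30), "palbociclib", 30),
                  (day(60), "palbociclib", 30)]),
            rules,
            grace_days=60,
        )
        assert len(ivs) == 1
        assert (ivs[0].start, ivs[0].end) == (day(0), day(89))

    def test_gap_beyond_grace_splits(self, rules):
        ivs = build_exposure_intervals(
            disp([(day(0), "palbociclib", 30), (day(120), "palbociclib", 30)]),
            rules,
            grace_days=60,
        )
        assert [(iv.start, iv.end) for iv in ivs] == [
            (day(0), day(29)),
            (day(120), day(149)),
        ]

    def test_single_dispensing_inclusive_end(self, rules):
        ivs = build_exposure_intervals(disp([(day(5), "letrozole", 28)]), rules)
        assert (ivs[0].start, ivs[0].end) == (day(5), day(32))

    def test_no_stockpiling_beyond_latest_coverage(self, rules):
        # early refill: coverage end stays at the max single-fill end
        ivs = build_exposure_intervals(
            disp([(day(0), "letrozole", 30), (day(10), "letrozole", 30)]), rules
        )
        assert ivs[0].end == day(39)

    def test_non_anticancer_drugs_ignored(self, rules):
        assert build_exposure_intervals(disp([(day(0), "ibuprofen", 30)]), rules) == []


class TestDeriveLines:
    def test_exchangeable_ai_agent_swap_single_line(self, rules):
        # CDK4/6i + letrozole, letrozole->exemestane at month 6, all stop
        # month 17: one line, discontinuation
        b = make_bundle(
            disp=refills("palbociclib", 0, 510)
            + refills("letrozole", 0, 150)
            + refills("exemestane", 180, 510)
        )
        lines = lines_for(b, rules)
        assert len(lines) == 1
        assert lines[0].drug_classes == {DrugClass.CDK46I, DrugClass.AI}
        assert lines[0].end_reason == EndReason.DISCONTINUATION
        assert lines[0].end == day(539)

    def test_switch_to_chemo_within_grace(self, rules):
        b = make_bundle(
            disp=refills("ribociclib", 0, 300)
            + refills("letrozole", 0, 300)
            + refills("chemotherapy", 340, 400)
        )
        lines = lines_for(b, rules)
        assert [l.end_reason for l in lines][:1] == [EndReason.SWITCH]
        assert lines[0].end == day(329)
        assert lines[1].start == day(340)
        assert lines[1].drug_classes == {DrugClass.CHEMO}

    def test_augmentation_creates_superset_line(self, rules):
        b = make_bundle(
            disp=refills("palbociclib", 0, 570)
            + refills("fulvestrant", 0, 570)
            + refills("chemotherapy", 120, 570)
        )
        lines = lines_for(b, rules)
        assert lines[0].end_reason == EndReason.AUGMENTATION
        assert lines[0].end == day(120)
        assert lines[1].start == day(120)
        assert lines[1].drug_classes == {
            DrugClass.CDK46I,
            DrugClass.FULVESTRANT,
            DrugClass.CHEMO,
        }

    def test_supply_gap_beyond_grace_advances_line(self, rules):
        b = make_bundle(
            disp=[(day(0), "palbociclib", 30), (day(120), "palbociclib", 30)]
        )
        lines = lines_for(b, rules)
        assert len(lines) == 2
        assert lines[0].end_reason == EndReason.DISCONTINUATION
        assert (lines[0].end, lines[1].start) == (day(29), day(120))

    def test_death_during_line_ends_it(self, rules):
        b = make_bundle(
            disp=refills("palbociclib", 0, 90) + refills("letrozole", 0, 90),
            death=day(100),
            last=day(100),
        )
        lines = lines_for(b, rules)
        assert len(lines) == 1
        assert lines[0].end_reason == EndReason.DEATH
        assert lines[0].end == day(100)

    def test_active_line_censored_at_cutoff(self, rules):
        b = make_bundle(disp=refills("palbociclib", 700, 729))
        lines = lines_for(b, rules, cutoff=CUTOFF)
        assert lines[0].end_reason == EndReason.END_OF_DATA
        assert lines[0].end == CUTOFF

    def test_unobservable_grace_window_censors(self, rules):
        # supply ends 20 days before cutoff: refill may exist beyond data
        b = make_bundle(disp=[(CUTOFF - dt.timedelta(days=49), "palbociclib", 30)])
        lines = lines_for(
            b, rules, index=CUTOFF - dt.timedelta(days=49), cutoff=CUTOFF
        )
        assert lines[0].end_reason == EndReason.END_OF_DATA
        assert lines[0].end == CUTOFF - dt.timedelta(days=20)

    def test_cdk_rechallenge_after_chemo_is_distinct_line(self, rules):
        b = make_bundle(
            disp=refills("palbociclib", 0, 150)
            + refills("letrozole", 0, 150)
            + refills("chemotherapy", 270, 360)
            + refills("ribociclib", 480, 570)
            + refills("fulvestrant", 480, 570)
        )
        lines = lines_for(b, rules)
        assert [regimen_category(l.drug_classes) for l in lines] == [
            "CDK4/6-based",
            "chemotherapy-based",
            "CDK4/6-based",
        ]

    def test_pre_index_exposure_excluded(self, rules):
        b = make_bundle(
            disp=[(day(-200), "letrozole", 30)] + refills("palbociclib", 0, 60)
        )
        lines = lines_for(b, rules)
        assert lines[0].drug_classes == {DrugClass.CDK46I}

    def test_no_eligible_dispensing_after_index_gives_no_lines(self, rules):
        b = make_bundle(disp=[(day(-100), "letrozole", 30)])
        assert lines_for(b, rules) == []

    def test_deterministic_partition(self, rules):
        b = make_bundle(
            disp=refills("palbociclib", 0, 300) + refills("chemotherapy", 400, 500)
        )
        assert lines_for(b, rules) == lines_for(b, rules)


def test_grace_monotonicity_on_synthetic_streams(rules, small_claims):
    """More generous grace periods can only merge lines, never split them."""
    for bundle in small_claims.bundles[:60]:
        counts = []
        for grace in (30, 60, 90):
            ivs = build_exposure_intervals(bundle.dispensings, rules, grace_days=grace)
            lines = derive_lines(
                ivs, day(-365 * 4), bundle.death_date, CUTOFF, grace_days=grace
            )
            counts.append(len(lines))
        assert counts[0] >= counts[1] >= counts[2]


def test_every_post_index_dispensing_covered_by_a_line(rules, small_claims):
    for bundle in small_claims.bundles[:60]:
        ivs = build_exposure_intervals(bundle.dispensings, rules)
        index = min(
            (e.date for e in bundle.dispensings
             if rules.classify_drug(e.drug) == DrugClass.CDK46I),
            default=None,
        )
        if index is None:
            continue
        lines = derive_lines(ivs, index, bundle.death_date, CUTOFF)
        last_end = max(l.end for l in lines)
        for ev in bundle.dispensings:
            if ev.date < index or rules.classify_drug(ev.drug) is DrugClass.NONE:
                continue
            inside = any(l.start <= ev.date <= l.end for l in lines)
            assert inside or ev.date > last_end


class TestRegimenLabels:
    @pytest.mark.parametrize(
        "classes, label",
        [
            ({DrugClass.CDK46I, DrugClass.FULVESTRANT}, "CDK46I+FULVESTRANT"),
            ({DrugClass.AI, DrugClass.CDK46I}, "CDK46I+AI"),
            ({DrugClass.CHEMO}, "CHEMO"),
            ({DrugClass.AI}, "AI"),
        ],
    )
    def test_canonical_labels(self, classes, label):
        assert regimen_label(classes) == label

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            regimen_label(set())

    @pytest.mark.parametrize(
        "classes, category",
        [
            ({DrugClass.CHEMO, DrugClass.CDK46I}, "chemotherapy-based"),
            ({DrugClass.CDK46I, DrugClass.AI}, "CDK4/6-based"),
            ({DrugClass.TAMOXIFEN}, "ET-based"),
            ({DrugClass.OTHER_ANTICANCER}, "other"),
        ],
    )
    def test_categories(self, classes, category):
        assert regimen_category(classes) == category
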