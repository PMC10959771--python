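import datetime as dt

import pytest

from claimlines import (
    build_cohort,
    find_index_date,
    meets_mbc_algorithm,
)
from claimlines.cohort import (
    RejectionReason,
    apply_eligibility,
    derive_baseline,
)
from claimlines.lines import build_exposure_intervals, derive_lines

from conftest import day, make_bundle, refills


def eligibility(bundle, rules, index=None):
    index = index if index is not None else find_index_date(bundle, rules)
    lines = []
    if index is not None:
        ivs = build_exposure_intervals(bundle.dispensings, rules)
        lines = derive_lines(ivs, index, bundle.death_date, dt.date(2019, 12, 31))
    return apply_eligibility(bundle, index, lines, rules)


class TestIndexDate:
    def test_earliest_of_drug_and_diagnosis(self, rules):
        b = make_bundle(
            disp=[(dt.date(2018, 3, 1), "fulvestrant", 30)],
            dx=[(dt.date(2018, 5, 1), "C780")],
        )
        assert find_index_date(b, rules) == dt.date(2018, 3, 1)

    def test_tamoxifen_alone_is_not_a_trigger(self, rules):
        b = make_bundle(disp=[(day(0), "tamoxifen", 30)])
        assert find_index_date(b, rules) is None

    def test_same_day_tie(self, rules):
        b = make_bundle(
            disp=[(day(0), "palbociclib", 30)], dx=[(day(0), "C780")]
        )
        assert find_index_date(b, rules) == day(0)

    def test_excluded_secondary_codes_do_not_trigger(self, rules):
        b = make_bundle(dx=[(day(0), "C773"), (day(5), "C792")])
        assert find_index_date(b, rules) is None


class TestMbcAlgorithm:
    def test_targeted_therapy_alone_qualifies(self, rules):
        assert meets_mbc_algorithm(
            make_bundle(disp=[(day(0), "ribociclib", 30)]), rules
        )

    def test_mets_code_followed_by_endocrine_qualifies(self, rules):
        b = make_bundle(
            disp=[(day(30), "letrozole", 30)], dx=[(day(0), "C780")]
        )
        assert meets_mbc_algorithm(b, rules)

    def test_same_day_counts_as_followed_by(self, rules):
        b = make_bundle(disp=[(day(0), "letrozole", 30)], dx=[(day(0), "C780")])
        assert meets_mbc_algorithm(b, rules)

    def test_her2_targeted_dispensing_disqualifies(self, rules):
        b = make_bundle(
            disp=[(day(0), "palbociclib", 30), (day(40), "trastuzumab", 30)]
        )
        assert not meets_mbc_algorithm(b, rules)

    def test_endocrine_before_mets_code_fails_order(self, rules):
        b = make_bundle(disp=[(day(0), "letrozole", 30)], dx=[(day(30), "C780")])
        assert not meets_mbc_algorithm(b, rules)

    def test_monotone_in_targeted_antitone_in_her2(self, rules):
        base = make_bundle(disp=[(day(0), "letrozole", 30)], dx=[(day(30), "C780")])
        assert not meets_mbc_algorithm(base, rules)
        with_cdk = base.with_events(
            dispensings=[type(base.dispensings[0])("P1", day(60), "abemaciclib", 30)]
        )
        assert meets_mbc_algorithm(with_cdk, rules)
        with_her2 = with_cdk.with_events(
            dispensings=[type(base.dispensings[0])("P1", day(90), "lapatinib", 30)]
        )
        assert not meets_mbc_algorithm(with_her2, rules)


def _standard_line1(start=dt.date(2018, 1, 1)):
    offset = (start - day(0)).days
    return refills("palbociclib", offset, offset + 120) + refills(
        "letrozole", offset, offset + 120
    )


class TestEligibility:
    def test_standard_patient_included(self, rules):
        record, reason = eligibility(make_bundle(disp=_standard_line1()), rules)
        assert reason is None
        assert record.arm == "CDK46I_AI"
        assert record.index_date == dt.date(2018, 1, 1)

    def test_under_18_rejected(self, rules):
        b = make_bundle(birth=dt.date(2000, 8, 1), disp=_standard_line1())
        _, reason = eligibility(b, rules)
        assert reason == RejectionReason.UNDER_AGE

    def test_index_after_accrual_era_rejected(self, rules):
        b = make_bundle(disp=_standard_line1(dt.date(2019, 8, 15)))
        _, reason = eligibility(b, rules)
        assert reason == RejectionReason.OUTSIDE_ERA

    def test_prior_primary_malignancy_rejected(self, rules):
        b = make_bundle(
            disp=_standard_line1(), dx=[(dt.date(2017, 3, 1), "C341")]
        )
        _, reason = eligibility(b, rules)
        assert reason == RejectionReason.PRIOR_PRIMARY

    def test_breast_and_secondary_codes_are_not_prior_primaries(self, rules):
        b = make_bundle(
            disp=_standard_line1(),
            dx=[(dt.date(2017, 3, 1), "C509"), (dt.date(2017, 6, 1), "C795")],
        )
        _, reason = eligibility(b, rules)
        assert reason is None

    def test_trial_participation_rejected(self, rules):
        b = make_bundle(trial=True, disp=_standard_line1())
        _, reason = eligibility(b, rules)
        assert reason == RejectionReason.TRIAL

    def test_cdk_monotherapy_first_line_rejected(self, rules):
        b = make_bundle(disp=refills("palbociclib", 0, 120))
        _, reason = eligibility(b, rules)
        assert reason == RejectionReason.LINE1_INELIGIBLE

    def test_both_partners_in_first_line_rejected(self, rules):
        b = make_bundle(
            disp=refills("palbociclib", 0, 120)
            + refills("letrozole", 0, 120)
            + refills("fulvestrant", 0, 120)
        )
        _, reason = eligibility(b, rules)
        assert reason == RejectionReason.LINE1_INELIGIBLE

    def test_fulvestrant_partner_sets_arm(self, rules):
        b = make_bundle(
            disp=refills("abemaciclib", 0, 120) + refills("fulvestrant", 0, 120)
        )
        record, reason = eligibility(b, rules)
        assert reason is None
        assert record.arm == "CDK46I_FULV"


class TestBaseline:
    def test_visceral_on_index_day_counts(self, rules):
        b = make_bundle(disp=_standard_line1(), dx=[(dt.date(2018, 1, 1), "C787")])
        cov = derive_baseline(b, dt.date(2018, 1, 1), dt.date(2018, 1, 1), rules)
        assert cov["visceral"] is True

    def test_bone_only_metastasis_is_not_visceral(self, rules):
        b = make_bundle(disp=_standard_line1(), dx=[(dt.date(2018, 1, 1), "C795")])
        cov = derive_baseline(b, dt.date(2018, 1, 1), dt.date(2018, 1, 1), rules)
        assert cov["visceral"] is False

    def test_prior_ai_makes_endocrine_resistant(self, rules):
        b = make_bundle(
            disp=[(dt.date(2017, 6, 15), "anastrozole", 30)] + _standard_line1()
        )
        cov = derive_baseline(b, dt.date(2018, 1, 1), dt.date(2018, 1, 1), rules)
        assert cov["endocrine_status"] == "resistant"
        assert cov["lookback_ai"] is True

    def test_no_prior_endocrine_is_sensitive(self, rules):
        cov = derive_baseline(
            make_bundle(disp=_standard_line1()),
            dt.date(2018, 1, 1),
            dt.date(2018, 1, 1),
            rules,
        )
        assert cov["endocrine_status"] == "sensitive"

    def test_endocrine_status_ignores_post_evidence_events(self, rules):
        # the first-line letrozole itself must not flag resistance
        b = make_bundle(disp=_standard_line1())
        cov = derive_baseline(b, dt.date(2018, 1, 1), dt.date(2018, 1, 1), rules)
        assert cov["endocrine_status"] == "sensitive"
        later = b.with_events(
            dispensings=[type(b.dispensings[0])("P1", dt.date(2018, 6, 1), "tamoxifen", 30)]
        )
        cov2 = derive_baseline(later, dt.date(2018, 1, 1), dt.date(2018, 1, 1), rules)
        assert cov2["endocrine_status"] == "sensitive"

    def test_menopause_proxy(self, rules):
        young = make_bundle(birth=dt.date(1980, 1, 2), disp=_standard_line1())
        cov = derive_baseline(young, dt.date(2018, 1, 1), dt.date(2018, 1, 1), rules)
        assert cov["menopausal_status"] == "pre"
        male = make_bundle(sex="M", disp=_standard_line1())
        cov = derive_baseline(male, dt.date(2018, 1, 1), dt.date(2018, 1, 1), rules)
        assert cov["menopausal_status"] == "not_applicable"

    def test_age_floored_to_one_decimal(self, rules):
        b = make_bundle(birth=dt.date(1955, 6, 15), disp=_standard_line1())
        cov = derive_baseline(b, dt.date(2018, 1, 1), dt.date(2018, 1, 1), rules)
        assert cov["age_at_index"] == 62.5

    def test_radiotherapy_flag_from_procedures(self, rules):
        b = make_bundle(disp=_standard_line1())
        cov = derive_baseline(
            b,
            dt.date(2018, 1, 1),
            dt.date(2018, 1, 1),
            rules,
            procedures=[(dt.date(2017, 9, 1), "radiotherapy")],
        )
        assert cov["lookback_radiotherapy"] is True
        assert cov["lookback_surgery"] is False


def test_attrition_partitions_population(rules, small_claims):
    records, _, attrition = build_cohort(
        list(small_claims.bundles), rules, procedures=small_claims.procedures
    )
    assert sum(attrition.values()) == len(small_claims.bundles)
    assert attrition["included"] == len(records)
    assert len(records) > 0
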