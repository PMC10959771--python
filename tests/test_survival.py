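import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claimlines import (
    DAYS_PER_MONTH,
    EndReason,
    km_by_group,
    km_fit,
    make_tttd,
    make_ttnt,
)
from claimlines.lines import LineOfTherapy
from claimlines.codesets import DrugClass

import pandas as pd

D = dt.date
CUTOFF = D(2019, 12, 31)


def line(start, end, reason, ordinal=1):
    return LineOfTherapy(
        patient_id="P1",
        ordinal=ordinal,
        start=start,
        end=end,
        drug_classes=frozenset({DrugClass.CDK46I, DrugClass.AI}),
        regimen_label="CDK46I+AI",
        end_reason=reason,
    )


class TestEndpointObservations:
    def test_tttd_discontinuation_event(self):
        l = line(D(2018, 1, 1), D(2018, 6, 30), EndReason.DISCONTINUATION)
        obs = make_tttd(l, None, CUTOFF)
        assert obs.event is True
        assert obs.time == pytest.approx(180 / DAYS_PER_MONTH)

    def test_tttd_censored_at_cutoff(self):
        l = line(D(2019, 6, 1), CUTOFF, EndReason.END_OF_DATA)
        obs = make_tttd(l, None, CUTOFF)
        assert obs.event is False
        assert obs.time == pytest.approx((CUTOFF - D(2019, 6, 1)).days / DAYS_PER_MONTH)

    def test_tttd_death_is_event(self):
        l = line(D(2018, 1, 1), D(2018, 9, 1), EndReason.DEATH)
        assert make_tttd(l, D(2018, 9, 1), CUTOFF).event is True

    def test_ttnt_event_at_next_line_start(self):
        l1 = line(D(2018, 1, 1), D(2018, 9, 1), EndReason.DISCONTINUATION)
        l2 = line(D(2018, 11, 1), D(2019, 3, 1), EndReason.DISCONTINUATION, ordinal=2)
        obs = make_ttnt(l1, l2, None, CUTOFF)
        assert obs.event is True
        assert obs.time == pytest.approx(304 / DAYS_PER_MONTH)

    def test_ttnt_death_censors(self):
        l1 = line(D(2018, 1, 1), D(2018, 8, 1), EndReason.DEATH)
        death = D(2018, 8, 1)
        obs = make_ttnt(l1, None, death, CUTOFF)
        assert obs.event is False
        assert obs.time == pytest.approx(212 / DAYS_PER_MONTH)

    def test_ttnt_censored_at_followup_end(self):
        l1 = line(D(2019, 1, 1), CUTOFF, EndReason.END_OF_DATA)
        obs = make_ttnt(l1, None, None, CUTOFF)
        assert obs.event is False
        assert obs.time == pytest.approx(364 / DAYS_PER_MONTH)

    def test_ttnt_inconsistent_ordering_rejected(self):
        l1 = line(D(2018, 5, 1), D(2018, 9, 1), EndReason.SWITCH)
        l2 = line(D(2018, 5, 1), D(2019, 1, 1), EndReason.SWITCH, ordinal=2)
        with pytest.raises(ValueError):
            make_ttnt(l1, l2, None, CUTOFF)


class TestKaplanMeier:
    def test_all_events_no_censoring(self):
        est = km_fit(times=[1, 2, 3, 4, 5], events=[1, 1, 1, 1, 1])
        assert np.allclose(est.survival, [0.8, 0.6, 0.4, 0.2, 0.0])
        assert est.median == 3

    def test_all_censored_flat_curve_no_median(self):
        est = km_fit(times=[1, 2, 3], events=[0, 0, 0])
        assert est.event_times.size == 0
        assert est.survival_at(99.0) == 1.0
        assert est.median is None

    def test_mixed_censoring_hand_computed(self):
        # 1+, 2, 3+, 4, 5+ : S(2)=0.75, S(4)=0.375, median 4
        est = km_fit(times=[1, 2, 3, 4, 5], events=[0, 1, 0, 1, 0])
        assert est.survival_at(2) == pytest.approx(0.75)
        assert est.survival_at(4) == pytest.approx(0.375)
        assert est.median == 4

    def test_censored_tied_with_event_stays_at_risk(self):
        est = km_fit(times=[2, 2, 5], events=[1, 0, 1])
        assert est.survival_at(2) == pytest.approx(2 / 3)

    def test_median_ci_brackets_median(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 300)
        c = rng.uniform(0, 30, 300)
        times, events = np.minimum(t, c), t <= c
        est = km_fit(times=times, events=events)
        lo, hi = est.median_ci
        assert lo is not None and hi is not None
        assert lo <= est.median <= hi

    def test_zero_length_censored_observations(self):
        est = km_fit(times=[0.0, 0.0], events=[0, 0])
        assert est.median is None
        assert est.survival_at(0.0) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_fit(times=[], events=[])

    @given(
        n=st.integers(5, 60),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_lifelines_estimator(self, n, seed):
        """Independent cross-check of S(t), and of the median, vs lifelines."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(seed)
        t = np.round(rng.exponential(12, n), 1) + 0.1
        c = np.round(rng.uniform(0, 25, n), 1) + 0.1
        times, events = np.minimum(t, c), t <= c
        est = km_fit(times=times, events=events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for ti, si in zip(est.event_times, est.survival):
            assert kmf.predict(ti) == pytest.approx(si, abs=1e-10)
        ll_median = kmf.median_survival_time_
        if est.median is None:
            assert np.isinf(ll_median)
        else:
            assert est.median == pytest.approx(ll_median)

    def test_no_censoring_median_is_lower_middle_order_statistic(self):
        rng = np.random.default_rng(3)
        for n in range(1, 9):
            for _ in range(20):
                t = np.round(rng.exponential(5, n), 2)
                est = km_fit(times=t, events=np.ones(n, bool))
                assert est.median == pytest.approx(sorted(t)[(n - 1) // 2])


def test_km_by_group_partitions_population():
    df = pd.DataFrame(
        {
            "time": [1, 2, 3, 4, 5, 6],
            "event": [1, 1, 0, 1, 0, 1],
            "arm": ["A", "A", "A", "B", "B", "B"],
        }
    )
    fits = km_by_group(df, "arm")
    assert sum(est.n for est in fits.values()) == len(df)
    assert set(fits) == {("A",), ("B",)}
    overall = km_by_group(df, "overall")
    assert overall[("overall",)].n == 6
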