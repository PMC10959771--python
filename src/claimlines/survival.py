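"""Real-world treatment endpoints and Kaplan–Meier estimation.

Two endpoints are built from derived lines of therapy:

* **TTTD** (time to treatment discontinuation): line start to the earliest of
  discontinuation (supply exhaustion with no refill inside the grace period),
  switch, augmentation, or death — all events; lines still active at the
  administrative cutoff are censored there.
* **TTNT** (time to next treatment): line start to the next line's start
  (event); patients without a subsequent line are *censored* at death or end
  of follow-up, whichever is earliest.  Death is censoring for TTNT but an
  event for TTTD — the reason TTNT medians exceed TTTD medians.

Times are reported in months (days / 30.4375).  The product-limit estimator,
Greenwood variance and the log(−log) median confidence bands are implemented
natively; an established survival library is used only as an independent
cross-check in the test suite.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lines import EndReason, LineOfTherapy

__all__ = [
    "DAYS_PER_MONTH",
    "SurvivalObservation",
    "SurvivalEstimate",
    "make_tttd",
    "make_ttnt",
    "km_fit",
    "km_by_group",
]

#: Fixed day→month conversion (mean Gregorian month length).
DAYS_PER_MONTH = 30.4375

_EVENT_REASONS = {
    EndReason.AUGMENTATION,
    EndReason.SWITCH,
    EndReason.DISCONTINUATION,
    EndReason.DEATH,
}


@dataclasses.dataclass(frozen=True)
class SurvivalObservation:
    """One (time, event) pair for one patient-line and endpoint."""

    patient_id: str
    line_ordinal: int
    time: float  # months, >= 0
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative follow-up time {self.time}")


def _months(days: int) -> float:
    return days / DAYS_PER_MONTH


def make_tttd(
    line: LineOfTherapy,
    death_date: dt.date | None,
    cutoff: dt.date,
) -> SurvivalObservation:
    """TTTD observation for one derived line.

    The line's end date already encodes the earliest terminating trigger
    (discontinuation/switch/augmentation date, or death); any terminating
    reason is an event, while ``end_of_data`` censors at the line end (the
    cutoff for lines still on supply).
    """
    event = line.end_reason in _EVENT_REASONS
    return SurvivalObservation(
        patient_id=line.patient_id,
        line_ordinal=line.ordinal,
        time=_months(line.duration_days),
        event=event,
    )


def make_ttnt(
    line: LineOfTherapy,
    next_line: LineOfTherapy | None,
    death_date: dt.date | None,
    followup_end: dt.date,
) -> SurvivalObservation:
    """TTNT observation: next-line start is the event, death censors.

    A next line starting the same day as death counts as the event (event
    precedence on ties).  Without a next line the observation is censored at
    ``min(death, followup_end)``.
    """
    if next_line is not None:
        if next_line.start <= line.start:
            raise ValueError(
                f"next line starts {next_line.start} on/before current line "
                f"start {line.start} for patient {line.patient_id}"
            )
        days = (next_line.start - line.start).days
        return SurvivalObservation(line.patient_id, line.ordinal, _months(days), True)
    end = followup_end
    if death_date is not None:
        end = min(end, death_date)
    days = max((end - line.start).days, 0)
    return SurvivalObservation(line.patient_id, line.ordinal, _months(days), False)


@dataclasses.dataclass(frozen=True)
class SurvivalEstimate:
    """Product-limit curve with Greenwood bands and median CI.

    ``event_times`` are the distinct event times; ``survival`` the curve
    immediately after each (non-increasing, S(0−)=1).  ``median`` is the
    smallest event time with S(t) ≤ 0.5, ``None`` when the curve never
    reaches 0.5.  The 95% CI for the median inverts the pointwise
    log(−log S) bands.
    """

    n: int
    n_events: int
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float | None
    median_ci: tuple[float | None, float | None]

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def km_fit(
    observations: Iterable[SurvivalObservation] | None = None,
    *,
    times: Sequence[float] | None = None,
    events: Sequence[bool] | None = None,
    alpha: float = 0.05,
) -> SurvivalEstimate:
    """Kaplan–Meier product-limit fit.

    Accepts either :class:`SurvivalObservation` records or raw
    ``times``/``events`` arrays.  At each distinct event time ``t_i`` with
    ``d_i`` events among ``n_i`` at risk, ``S(t) = Π (1 − d_i/n_i)``.
    Censored observations tied with an event time remain at risk for it
    (standard convention).  Variance is Greenwood's; confidence bands are on
    the log(−log S) scale; the median CI inverts those bands
    (Brookmeyer–Crowley).
    """
    if observations is not None:
        obs = list(observations)
        t = np.asarray([o.time for o in obs], dtype=float)
        e = np.asarray([o.event for o in obs], dtype=bool)
    else:
        if times is None or events is None:
            raise ValueError("provide observations or both times and events")
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("km_fit requires at least one observation")
    if np.any(t < 0):
        raise ValueError("negative times")

    n = t.size
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]

    event_times = np.unique(t[e])
    at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    for i, ti in enumerate(event_times):
        at_risk[i] = int(np.sum(t >= ti))
        d[i] = int(np.sum((t == ti) & e))

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d / at_risk
        survival = np.cumprod(frac)
        # Greenwood cumulative sum for the log(-log) transform
        gw_terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
        gw_cum = np.cumsum(gw_terms)

    z = _norm_ppf(1.0 - alpha / 2.0)
    ci_lower = np.ones_like(survival)
    ci_upper = np.ones_like(survival)
    for i, s in enumerate(survival):
        if s <= 0.0 or not np.isfinite(gw_cum[i]):
            ci_lower[i] = 0.0
            ci_upper[i] = 0.0 if s <= 0.0 else 1.0
            continue
        if s >= 1.0:
            ci_lower[i] = ci_upper[i] = 1.0
            continue
        se = math.sqrt(gw_cum[i]) / abs(math.log(s))
        theta = math.log(-math.log(s))
        ci_lower[i] = math.exp(-math.exp(theta + z * se))
        ci_upper[i] = math.exp(-math.exp(theta - z * se))

    median = _first_crossing(event_times, survival, 0.5)
    median_ci = (
        _first_crossing(event_times, ci_lower, 0.5),
        _first_crossing(event_times, ci_upper, 0.5),
    )

    return SurvivalEstimate(
        n=n,
        n_events=int(e.sum()),
        event_times=event_times,
        survival=survival,
        at_risk=at_risk,
        events=d,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        median=median,
        median_ci=median_ci,
    )


def _first_crossing(times: np.ndarray, curve: np.ndarray, level: float) -> float | None:
    below = np.nonzero(curve <= level)[0]
    return float(times[below[0]]) if below.size else None


def _norm_ppf(p: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(p))


def km_by_group(
    observations: pd.DataFrame,
    grouping: str | Sequence[str] = "overall",
    alpha: float = 0.05,
) -> Mapping[tuple, SurvivalEstimate]:
    """Fit one KM curve per stratum of an observation table.

    ``observations`` needs ``time`` and ``event`` columns plus any stratifier
    columns named by ``grouping`` (``"overall"`` fits a single curve).
    Empty strata cannot arise from a groupby; strata are keyed by tuples of
    their level values.
    """
    if observations.empty:
        raise ValueError("no observations to fit")
    if grouping == "overall" or grouping == ["overall"]:
        return {("overall",): km_fit(
            times=observations["time"].to_numpy(),
            events=observations["event"].to_numpy(dtype=bool),
            alpha=alpha,
        )}
    keys = [grouping] if isinstance(grouping, str) else list(grouping)
    out: dict[tuple, SurvivalEstimate] = {}
    for key, grp in observations.groupby(keys, sort=True, observed=True):
        key_t = key if isinstance(key, tuple) else (key,)
        out[key_t] = km_fit(
            times=grp["time"].to_numpy(),
            events=grp["event"].to_numpy(dtype=bool),
            alpha=alpha,
        )
    return out
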