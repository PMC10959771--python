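"""End-to-end pipeline: claims in, cohort / lines / endpoints / tables out.

Given a claims CSV directory the pipeline phenotypes the cohort, derives
lines of therapy, builds TTTD/TTNT observations, fits Kaplan–Meier curves
by stratum and writes every output as deterministic text files:
``cohort.csv``, ``lines.csv``, ``survival.csv``, ``table1.csv``,
``table2.csv``, ``sequences.csv``, ``attrition.json``, per-curve
step-function CSVs under ``curves/`` and a parameter ``run.log``.  Running
twice on the same inputs produces byte-identical outputs.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .claims import PatientBundle, read_claims, read_procedures
from .codesets import CodeRuleSet, load_code_rules
from .cohort import DATA_CUTOFF, CohortRecord, build_cohort
from .lines import DEFAULT_COMBO_WINDOW_DAYS, DEFAULT_GRACE_DAYS, LineOfTherapy
from .report import (
    baseline_table,
    cohort_to_frame,
    history_table,
    lines_to_frame,
    sequence_counts,
)
from .survival import SurvivalEstimate, km_fit, make_tttd, make_ttnt

__all__ = ["PipelineResult", "build_observations", "survival_table", "run_pipeline"]


def build_observations(
    records: Sequence[CohortRecord],
    lines_by_patient: Mapping[str, Sequence[LineOfTherapy]],
    cutoff: dt.date = DATA_CUTOFF,
) -> pd.DataFrame:
    """Per patient-line TTTD and TTNT observations with stratifiers.

    Columns: patient_id, arm (first-line arm), endocrine_status, ordinal,
    endpoint ('tttd' | 'ttnt'), time (months), event.
    """
    rows = []
    by_id = {r.patient_id: r for r in records}
    for pid in sorted(by_id):
        rec = by_id[pid]
        lines = list(lines_by_patient.get(pid, ()))
        death = rec.followup_end if rec.death_observed else None
        for k, line in enumerate(lines):
            tttd = make_tttd(line, death, cutoff)
            nxt = lines[k + 1] if k + 1 < len(lines) else None
            ttnt = make_ttnt(line, nxt, death, rec.followup_end)
            for endpoint, obs in (("tttd", tttd), ("ttnt", ttnt)):
                rows.append(
                    {
                        "patient_id": pid,
                        "arm": rec.arm,
                        "endocrine_status": rec.endocrine_status,
                        "ordinal": line.ordinal,
                        "endpoint": endpoint,
                        "time": obs.time,
                        "event": obs.event,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "arm",
            "endocrine_status",
            "ordinal",
            "endpoint",
            "time",
            "event",
        ],
    )


def _fit_row(endpoint: str, stratum: str, group: pd.DataFrame) -> dict:
    est = km_fit(
        times=group["time"].to_numpy(), events=group["event"].to_numpy(dtype=bool)
    )
    lo, hi = est.median_ci
    fmt = lambda x: round(x, 4) if x is not None else ""
    return {
        "endpoint": endpoint,
        "stratum": stratum,
        "n": est.n,
        "events": est.n_events,
        "median_months": fmt(est.median),
        "ci_low": fmt(lo),
        "ci_high": fmt(hi),
    }


def survival_table(observations: pd.DataFrame, max_line: int = 3) -> pd.DataFrame:
    """Median (95% CI) TTTD and TTNT per line and stratum.

    Strata per endpoint: each line ordinal overall and by first-line arm,
    plus line 1 split by arm × endocrine status.  Empty strata are omitted.
    """
    rows = []
    for endpoint in ("tttd", "ttnt"):
        eobs = observations[observations["endpoint"] == endpoint]
        for ordinal in range(1, max_line + 1):
            lobs = eobs[eobs["ordinal"] == ordinal]
            if lobs.empty:
                continue
            rows.append(_fit_row(endpoint, f"line{ordinal}|overall", lobs))
            for arm, grp in lobs.groupby("arm", sort=True):
                rows.append(_fit_row(endpoint, f"line{ordinal}|{arm}", grp))
            if ordinal == 1:
                for (arm, endo), grp in lobs.groupby(
                    ["arm", "endocrine_status"], sort=True
                ):
                    rows.append(_fit_row(endpoint, f"line1|{arm}|{endo}", grp))
    return pd.DataFrame(
        rows,
        columns=["endpoint", "stratum", "n", "events", "median_months", "ci_low", "ci_high"],
    )


@dataclass(frozen=True)
class PipelineResult:
    cohort: pd.DataFrame
    lines: pd.DataFrame
    observations: pd.DataFrame
    survival: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    sequences: pd.DataFrame
    attrition: dict
    records: tuple[CohortRecord, ...]
    lines_by_patient: Mapping[str, Sequence[LineOfTherapy]]


def analyze_bundles(
    bundles: Sequence[PatientBundle],
    rules: CodeRuleSet | None = None,
    procedures: Mapping[str, Sequence[tuple[dt.date, str]]] | None = None,
    grace_days: int = DEFAULT_GRACE_DAYS,
    combo_window_days: int = DEFAULT_COMBO_WINDOW_DAYS,
    cutoff: dt.date = DATA_CUTOFF,
) -> PipelineResult:
    """Run the full analysis in memory (no file I/O)."""
    rules = rules or load_code_rules()
    records, lines_by_patient, attrition = build_cohort(
        bundles,
        rules,
        procedures=procedures,
        grace_days=grace_days,
        combo_window_days=combo_window_days,
        cutoff=cutoff,
    )
    cohort_df = cohort_to_frame(records)
    observations = build_observations(records, lines_by_patient, cutoff)
    if not cohort_df.empty:
        survival = survival_table(observations)
        table1 = baseline_table(cohort_df)
        table2 = history_table(cohort_df)
        sequences = sequence_counts(cohort_df, lines_by_patient)
    else:
        survival = table1 = table2 = sequences = pd.DataFrame()
    return PipelineResult(
        cohort=cohort_df,
        lines=lines_to_frame(lines_by_patient),
        observations=observations,
        survival=survival,
        table1=table1,
        table2=table2,
        sequences=sequences,
        attrition=dict(attrition),
        records=tuple(records),
        lines_by_patient=lines_by_patient,
    )


def _write_curve_csvs(observations: pd.DataFrame, out: Path) -> None:
    curves = out / "curves"
    curves.mkdir(exist_ok=True)
    for endpoint in ("tttd", "ttnt"):
        line1 = observations[
            (observations["endpoint"] == endpoint) & (observations["ordinal"] == 1)
        ]
        if line1.empty:
            continue
        strata: list[tuple[str, pd.DataFrame]] = [("overall", line1)]
        strata += [(str(a), g) for a, g in line1.groupby("arm", sort=True)]
        for name, grp in strata:
            est: SurvivalEstimate = km_fit(
                times=grp["time"].to_numpy(), events=grp["event"].to_numpy(dtype=bool)
            )
            est.to_frame().round(6).to_csv(
                curves / f"{endpoint}_line1_{name}.csv", index=False
            )


def run_pipeline(
    claims_dir: str | Path,
    out_dir: str | Path,
    codes_path: str | Path | None = None,
    grace_days: int = DEFAULT_GRACE_DAYS,
    combo_window_days: int = DEFAULT_COMBO_WINDOW_DAYS,
    cutoff: dt.date = DATA_CUTOFF,
) -> PipelineResult:
    """File-to-file pipeline run; see module docstring for outputs."""
    claims_dir, out = Path(claims_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rules = load_code_rules(codes_path)
    bundles = read_claims(claims_dir)
    procedures = read_procedures(claims_dir)
    result = analyze_bundles(
        bundles,
        rules,
        procedures=procedures,
        grace_days=grace_days,
        combo_window_days=combo_window_days,
        cutoff=cutoff,
    )

    result.cohort.to_csv(out / "cohort.csv", index=False)
    result.lines.to_csv(out / "lines.csv", index=False)
    result.observations.round(6).to_csv(out / "observations.csv", index=False)
    result.survival.to_csv(out / "survival.csv", index=False)
    result.table1.to_csv(out / "table1.csv", index=False)
    result.table2.to_csv(out / "table2.csv", index=False)
    result.sequences.to_csv(out / "sequences.csv", index=False)
    (out / "attrition.json").write_text(
        json.dumps(result.attrition, indent=2) + "\n", encoding="utf-8"
    )
    _write_curve_csvs(result.observations, out)

    log_lines = [
        f"claimlines {__version__}",
        f"code list version: {rules.version}",
        f"claims dir: {claims_dir.name}",
        f"grace_days: {grace_days}",
        f"combo_window_days: {combo_window_days}",
        f"cutoff: {cutoff.isoformat()}",
        f"input patients: {sum(result.attrition.values())}",
        f"cohort size: {result.attrition.get('included', 0)}",
    ]
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return result
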