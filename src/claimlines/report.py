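"""Study summary surfaces: baseline table, treatment history, sequences.

Reporting conventions match administrative-claims publications: cells show
``N (%)``, percentages are computed from their own printed counts with
half-up rounding, counts between 1 and 9 are masked as ``< 10`` (the
small-cell disclosure rule of nationwide claims databases), and the
menopausal row uses the *female* patients of each column as denominator.
"""

from __future__ import annotations

import datetime as dt
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .cohort import CohortRecord
from .codesets import CHARLSON_CATEGORIES
from .lines import LineOfTherapy, regimen_category

__all__ = [
    "percent",
    "format_cell",
    "cohort_to_frame",
    "lines_to_frame",
    "baseline_table",
    "history_table",
    "sequence_counts",
    "SMALL_CELL_THRESHOLD",
]

SMALL_CELL_THRESHOLD = 10

ARM_COLUMNS = ["overall", "CDK46I_AI", "CDK46I_FULV"]

SEQUENCE_CATEGORIES = (
    "chemotherapy-based",
    "CDK4/6-based",
    "ET-based",
    "other",
    "no further treatment observed",
)


def percent(numerator: int, denominator: int, decimals: int = 1) -> float | None:
    """Half-up rounded percentage ``100·n/d``; ``None`` when ``d == 0``.

    Half-up (not banker's) rounding reproduces published table cells, e.g.
    82.65 → 82.7 at one decimal.
    """
    if denominator == 0:
        return None
    if not (0 <= numerator <= denominator):
        raise ValueError(f"numerator {numerator} outside [0, {denominator}]")
    exact = Decimal(100 * numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(q, rounding=ROUND_HALF_UP))


def format_cell(count: int, denominator: int, decimals: int = 1) -> str:
    """``N (%)`` cell with small-cell masking (1–9 → ``< 10``)."""
    if 0 < count < SMALL_CELL_THRESHOLD:
        return "< 10"
    pct = percent(count, denominator, decimals)
    return f"{count}" if pct is None else f"{count} ({pct:.{decimals}f})"


def cohort_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Cohort records as a tidy DataFrame (one row per patient)."""
    return pd.DataFrame([vars(r) for r in records])


def lines_to_frame(lines_by_patient: Mapping[str, Sequence[LineOfTherapy]]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": line.patient_id,
            "ordinal": line.ordinal,
            "start": line.start.isoformat(),
            "end": line.end.isoformat(),
            "regimen_label": line.regimen_label,
            "regimen_category": regimen_category(line.drug_classes),
            "end_reason": line.end_reason.value,
        }
        for pid in sorted(lines_by_patient)
        for line in lines_by_patient[pid]
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "ordinal",
            "start",
            "end",
            "regimen_label",
            "regimen_category",
            "end_reason",
        ],
    )


def _column_frames(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {
        "overall": cohort,
        "CDK46I_AI": cohort[cohort["arm"] == "CDK46I_AI"],
        "CDK46I_FULV": cohort[cohort["arm"] == "CDK46I_FULV"],
    }


def baseline_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Baseline demographics and clinical characteristics by first-line arm.

    Rows: cohort size, calendar year of first mBC evidence (masked small
    cells), age median (IQR) and min–max, female, visceral metastases,
    menopausal status (female denominator), and Charlson category.
    """
    if cohort.empty:
        raise ValueError("baseline_table requires a non-empty cohort")
    cols = _column_frames(cohort)
    rows: list[dict] = []

    def add(label: str, cells: Mapping[str, str]) -> None:
        rows.append({"label": label, **{c: cells[c] for c in ARM_COLUMNS}})

    add("N", {c: str(len(df)) for c, df in cols.items()})

    years = sorted(cohort["index_year"].unique())
    for year in years:
        add(
            f"mBC evidence in {year}, N (%)",
            {
                c: format_cell(int((df["index_year"] == year).sum()), len(df))
                for c, df in cols.items()
            },
        )

    def age_cells(df: pd.DataFrame) -> tuple[str, str]:
        a = df["age_at_index"]
        return (
            f"{a.median():.1f} ({a.quantile(0.25):.1f}-{a.quantile(0.75):.1f})",
            f"{a.min():.1f}: {a.max():.1f}",
        )

    add("Age, median (IQR)", {c: age_cells(df)[0] for c, df in cols.items()})
    add("Age, min: max", {c: age_cells(df)[1] for c, df in cols.items()})
    add(
        "Female, N (%)",
        {
            c: format_cell(int((df["sex"] == "F").sum()), len(df))
            for c, df in cols.items()
        },
    )
    add(
        "Visceral metastases, N (%)",
        {c: format_cell(int(df["visceral"].sum()), len(df)) for c, df in cols.items()},
    )
    # menopausal proxy: denominator is female patients within each column
    add(
        "Post-menopausal (age >= 50), N (% of female)",
        {
            c: format_cell(
                int((df["menopausal_status"] == "post").sum()),
                int((df["sex"] == "F").sum()),
            )
            for c, df in cols.items()
        },
    )
    for cat in CHARLSON_CATEGORIES:
        add(
            f"Charlson category {cat}, N (%)",
            {
                c: format_cell(int((df["charlson_category"] == cat).sum()), len(df))
                for c, df in cols.items()
            },
        )
    return pd.DataFrame(rows, columns=["label", *ARM_COLUMNS])


_HISTORY_ROWS = [
    ("Any cancer medication, N (%)", "lookback_any_cancer_med"),
    ("AI, N (%)", "lookback_ai"),
    ("Tamoxifen, N (%)", "lookback_tamoxifen"),
    ("Chemotherapy, N (%)", "lookback_chemo"),
    ("Radiotherapy, N (%)", "lookback_radiotherapy"),
    ("Surgery, N (%)", "lookback_surgery"),
]


def history_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """One-year pre-index treatment history by arm (rows are not exclusive).

    The final row is the endocrine-sensitivity proxy: no AI/tamoxifen in the
    year before first mBC evidence.
    """
    if cohort.empty:
        raise ValueError("history_table requires a non-empty cohort")
    cols = _column_frames(cohort)
    rows = []
    for label, field in _HISTORY_ROWS:
        rows.append(
            {
                "label": label,
                **{
                    c: format_cell(int(df[field].sum()), len(df))
                    for c, df in cols.items()
                },
            }
        )
    rows.append(
        {
            "label": "No evidence of AI or tamoxifen (endocrine sensitivity proxy), N (%)",
            **{
                c: format_cell(
                    int((df["endocrine_status"] == "sensitive").sum()), len(df)
                )
                for c, df in cols.items()
            },
        }
    )
    return pd.DataFrame(rows, columns=["label", *ARM_COLUMNS])


def sequence_counts(
    cohort: pd.DataFrame,
    lines_by_patient: Mapping[str, Sequence[LineOfTherapy]],
    max_depth: int = 3,
) -> pd.DataFrame:
    """Treatment-sequence transition counts by first-line arm.

    For each depth ≥ 2 the regimen at that line is categorised
    (chemotherapy-based / CDK4/6-based rechallenge / ET-based / other), with
    patients lacking that line counted as 'no further treatment observed';
    categories therefore partition each arm at every depth.
    """
    rows = []
    for arm, df in cohort.groupby("arm", sort=True):
        pids = df["patient_id"].tolist()
        for depth in range(2, max_depth + 1):
            counts = dict.fromkeys(SEQUENCE_CATEGORIES, 0)
            for pid in pids:
                lines = lines_by_patient.get(pid, [])
                if len(lines) >= depth:
                    counts[regimen_category(lines[depth - 1].drug_classes)] += 1
                else:
                    counts["no further treatment observed"] += 1
            for cat in SEQUENCE_CATEGORIES:
                rows.append(
                    {
                        "arm": arm,
                        "depth": depth,
                        "category": cat,
                        "count": counts[cat],
                        "arm_n": len(pids),
                    }
                )
    return pd.DataFrame(rows, columns=["arm", "depth", "category", "count", "arm_n"])
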