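"""Guardian survey cohort: schema, validation, scoring rules and CSV I/O.

The cohort is a per-respondent table holding four self-report instruments —
the nine-item depression questionnaire PHQ-9 (items 0–3), the seven-item
anxiety scale GAD-7 (items 0–3), a single 0–10 fatigue numeric rating scale,
and the two global quality-of-life items of the WHOQOL-BREF (1–5) — together
with demographic and clinical covariates.  Scoring sums each instrument's
items; a respondent is flagged as having clinically relevant depression when
the PHQ-9 total reaches the screening cutoff (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PHQ9_COLS",
    "GAD7_COLS",
    "QOL_COLS",
    "BOOL_COLS",
    "CATEGORICAL_LEVELS",
    "ALL_COLUMNS",
    "DEPRESSION_CUTOFF",
    "CohortValidationError",
    "CohortTable",
    "ScoredCohort",
    "score_phq9",
    "score_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
]

PHQ9_COLS = [f"phq9_{i}" for i in range(1, 10)]
GAD7_COLS = [f"gad7_{i}" for i in range(1, 8)]
QOL_COLS = ["qol_1", "qol_2"]

#: boolean covariates, stored as 0/1 integers in CSV
BOOL_COLS = [
    "married",
    "employed",
    "rural",
    "physical_disease",
    "visit_difficulty",
    "medication_compliance_good",
]

CATEGORICAL_LEVELS = {
    "sex": ("male", "female"),
    "education": ("below_senior", "senior_or_above"),
    "financial_status": ("poor", "fair", "good"),
    "social_media_freq": ("none_minimal", "sometimes", "often"),
    "diagnosis": ("mdd", "bipolar", "schizophrenia", "other"),
}

#: per-column inclusive integer ranges for the scale items
ITEM_RANGES = {
    **{c: (0, 3) for c in PHQ9_COLS},
    **{c: (0, 3) for c in GAD7_COLS},
    "fatigue": (0, 10),
    **{c: (1, 5) for c in QOL_COLS},
}

ALL_COLUMNS = (
    ["respondent_id"]
    + PHQ9_COLS
    + GAD7_COLS
    + ["fatigue"]
    + QOL_COLS
    + ["age", "sex"]
    + BOOL_COLS
    + ["education", "financial_status", "social_media_freq", "diagnosis"]
)

DEPRESSION_CUTOFF = 5


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema.

    Carries the offending row index and column name when known.
    """

    def __init__(self, message: str, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


def _check_items(values, lo, hi, column):
    arr = np.asarray(values)
    if arr.size and not np.issubdtype(arr.dtype, np.number):
        bad = next(
            i for i, v in enumerate(values) if not isinstance(v, (int, np.integer))
        )
        raise CohortValidationError(
            f"column {column!r}: unparseable value {values[bad]!r} at row {bad}",
            row=bad,
            column=column,
        )
    if arr.size and np.any(arr != np.floor(arr)):
        bad = int(np.argmax(arr != np.floor(arr)))
        raise CohortValidationError(
            f"column {column!r}: non-integer value {arr[bad]} at row {bad}",
            row=bad,
            column=column,
        )
    out = (arr < lo) | (arr > hi)
    if np.any(out):
        bad = int(np.argmax(out))
        raise CohortValidationError(
            f"column {column!r}: value {arr[bad]} at row {bad} "
            f"outside allowed range {lo}..{hi}",
            row=bad,
            column=column,
        )


@dataclass(frozen=True)
class CohortTable:
    """Validated per-respondent survey table.

    Construct with :meth:`from_dataframe` (or :func:`read_cohort_csv`), which
    enforces the schema: item ranges, categorical levels, no missing values.
    Rows with any missing scale item are dropped (complete-case analysis) and
    the count is recorded in ``n_dropped``.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, drop_incomplete: bool = True) -> "CohortTable":
        df = df.copy()
        missing_cols = [c for c in ALL_COLUMNS if c not in df.columns and c != "respondent_id"]
        if missing_cols:
            raise CohortValidationError(
                f"missing required column(s): {', '.join(missing_cols)}",
                column=missing_cols[0],
            )
        if "respondent_id" not in df.columns:
            df["respondent_id"] = [f"R{i + 1:06d}" for i in range(len(df))]
        df["respondent_id"] = df["respondent_id"].astype(str)

        scale_cols = list(ITEM_RANGES) + ["age"]
        n_before = len(df)
        if drop_incomplete:
            df = df.dropna(subset=scale_cols).reset_index(drop=True)
        n_dropped = n_before - len(df)
        if df.isna().any().any():
            col = df.columns[df.isna().any()][0]
            row = int(df[col].isna().idxmax())
            raise CohortValidationError(
                f"missing value in column {col!r} at row {row}", row=row, column=col
            )

        for col, (lo, hi) in ITEM_RANGES.items():
            _check_items(df[col].to_numpy(), lo, hi, col)
            df[col] = df[col].astype(np.int64)
        for col in BOOL_COLS:
            vals = df[col].to_numpy()
            if not np.isin(vals, [0, 1, True, False]).all():
                bad = int(np.argmax(~np.isin(vals, [0, 1, True, False])))
                raise CohortValidationError(
                    f"column {col!r}: value {vals[bad]!r} at row {bad} is not 0/1",
                    row=bad,
                    column=col,
                )
            df[col] = df[col].astype(np.int64)
        for col, levels in CATEGORICAL_LEVELS.items():
            vals = df[col].astype(str)
            ok = vals.isin(levels)
            if not ok.all():
                bad = int((~ok).idxmax())
                raise CohortValidationError(
                    f"column {col!r}: unknown level {vals[bad]!r} at row {bad}; "
                    f"expected one of {levels}",
                    row=bad,
                    column=col,
                )
            df[col] = vals
        ages = df["age"].to_numpy(dtype=float)
        if np.any(ages <= 0):
            bad = int(np.argmax(ages <= 0))
            raise CohortValidationError(
                f"column 'age': non-positive value {ages[bad]} at row {bad}",
                row=bad,
                column="age",
            )
        df["age"] = ages
        return cls(data=df[ALL_COLUMNS], n_dropped=n_dropped)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class ScoredCohort:
    """Cohort with instrument totals and the depression flag attached.

    ``phq9_total`` in 0–27, ``gad7_total`` in 0–21, ``qol_global`` (sum of the
    two WHOQOL-BREF items) in 2–10, and ``depressed`` = PHQ-9 total >= cutoff.
    """

    data: pd.DataFrame
    cutoff: int = DEPRESSION_CUTOFF
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_depressed(self) -> int:
        return int(self.data["depressed"].sum())

    @property
    def n_nondepressed(self) -> int:
        return self.n - self.n_depressed

    @property
    def prevalence(self) -> float:
        return self.n_depressed / self.n

    def __len__(self) -> int:
        return len(self.data)


def score_phq9(items) -> tuple[int, bool]:
    """Score one respondent's PHQ-9: total and the depression screen flag.

    Parameters
    ----------
    items : sequence of 9 integers, each in 0..3.

    Returns
    -------
    (total, depressed) with ``depressed = total >= 5``.
    """
    items = list(items)
    if len(items) != 9:
        raise CohortValidationError(
            f"PHQ-9 requires exactly 9 items, got {len(items)}"
        )
    for i, v in enumerate(items, start=1):
        if not isinstance(v, (int, np.integer)) or not (0 <= int(v) <= 3):
            raise CohortValidationError(
                f"PHQ-9 item {i} value {v!r} outside allowed range 0..3",
                column=f"phq9_{i}",
            )
    total = int(sum(items))
    return total, total >= DEPRESSION_CUTOFF


def score_cohort(table: CohortTable, cutoff: int = DEPRESSION_CUTOFF) -> ScoredCohort:
    """Attach instrument totals and the depression flag to a validated cohort."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    df = table.data.copy()
    df["phq9_total"] = df[PHQ9_COLS].sum(axis=1)
    df["gad7_total"] = df[GAD7_COLS].sum(axis=1)
    df["qol_global"] = df[QOL_COLS].sum(axis=1)
    df["depressed"] = (df["phq9_total"] >= cutoff).astype(np.int64)
    return ScoredCohort(data=df, cutoff=cutoff, n_dropped=table.n_dropped)


def read_cohort_csv(path, drop_incomplete: bool = True) -> CohortTable:
    """Read and validate a cohort CSV (UTF-8, header row, schema columns)."""
    try:
        df = pd.read_csv(path, dtype={"respondent_id": str})
    except ValueError as exc:
        raise CohortValidationError(f"unparseable CSV {path}: {exc}") from exc
    return CohortTable.from_dataframe(df, drop_incomplete=drop_incomplete)


def write_cohort_csv(table, path) -> None:
    """Write a cohort (or scored cohort) to CSV; round-trips exactly."""
    table.data.to_csv(path, index=False)
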