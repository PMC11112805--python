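"""Measurement scale and cohort data model.

The default scale is the Karolinska Exhaustion Disorder Scale (KEDS):
nine self-rated symptom items, each scored on a seven-point scale from
0 to 6, giving a total score from 0 to 54.  A total of 19 or above
indicates "at risk"; a reduction of 9 points or more counts as reliable
change.  All constants live in :class:`ScaleDefinition` so that other
ordinal scales can be analysed with the same pipeline.

A cohort is a long-format table of one record per subject per timepoint
with the nine item scores; analyses are complete-case per timepoint.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical ordering of the five study waves.
TIMEPOINTS: tuple[str, ...] = (
    "assessment",
    "start",
    "midpoint",
    "end",
    "followup12m",
)

#: Short machine-friendly item keys, in scale order.
ITEM_KEYS: tuple[str, ...] = (
    "concentration",
    "memory",
    "physical_stamina",
    "mental_stamina",
    "recovery",
    "sleep",
    "sensory_sensitivity",
    "experience_of_demands",
    "irritation_anger",
)


class CohortValidationError(ValueError):
    """Raised when cohort data violates the scale or uniqueness contract."""


@dataclass(frozen=True)
class ScaleDefinition:
    """An ordinal symptom scale with clinical-change thresholds.

    Parameters
    ----------
    item_labels
        Ordered item names; the network node labels.
    item_min, item_max
        Inclusive score bounds per item.
    risk_cutoff
        Total score at or above which a subject is considered at risk.
    reliable_change
        Minimum total-score reduction that counts as reliable improvement.
    """

    item_labels: tuple[str, ...] = ITEM_KEYS
    item_min: int = 0
    item_max: int = 6
    risk_cutoff: int = 19
    reliable_change: int = 9

    def __post_init__(self) -> None:
        if self.item_max <= self.item_min:
            raise ValueError("item_max must exceed item_min")
        if len(self.item_labels) != len(set(self.item_labels)):
            raise ValueError("item labels must be unique")
        if not (0 <= self.risk_cutoff <= self.n_items * self.item_max):
            raise ValueError("risk_cutoff outside achievable total range")
        if self.reliable_change <= 0:
            raise ValueError("reliable_change must be positive")

    @property
    def n_items(self) -> int:
        return len(self.item_labels)

    @property
    def max_total(self) -> int:
        """Largest achievable total score (54 for KEDS)."""
        return self.n_items * self.item_max


#: The KEDS scale with its published constants.
KEDS = ScaleDefinition()


@dataclass
class CohortTable:
    """Validated per-subject, per-timepoint item responses.

    ``data`` is wide: one row per (subject_id, timepoint) with one column
    per item; missing item scores are NaN.  Absent rows mean the subject
    did not respond at that wave at all.
    """

    data: pd.DataFrame
    scale: ScaleDefinition = field(default_factory=lambda: KEDS)
    timepoints: tuple[str, ...] = TIMEPOINTS

    def __post_init__(self) -> None:
        _validate_cohort_frame(self.data, self.scale, self.timepoints)

    @property
    def subjects(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def at_timepoint(self, timepoint: str) -> pd.DataFrame:
        if timepoint not in self.timepoints:
            raise KeyError(f"unknown timepoint {timepoint!r}")
        return self.data[self.data["timepoint"] == timepoint]

    def present_timepoints(self) -> list[str]:
        """Waves that actually occur in the data, in canonical order."""
        seen = set(self.data["timepoint"])
        return [t for t in self.timepoints if t in seen]


@dataclass
class TimepointMatrix:
    """Complete-case item-score matrix for one wave.

    Rows are subjects with all items present; columns follow the scale's
    item order.  This is the input to every network estimation step.
    """

    values: np.ndarray  # (n_subjects, n_items) integer scores
    subject_ids: np.ndarray
    timepoint: str
    scale: ScaleDefinition = field(default_factory=lambda: KEDS)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != self.scale.n_items:
            raise ValueError("matrix must be n_subjects x n_items")
        if np.isnan(np.asarray(self.values, dtype=float)).any():
            raise ValueError("TimepointMatrix must be complete-case")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids must align with rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _validate_cohort_frame(
    df: pd.DataFrame, scale: ScaleDefinition, timepoints: Sequence[str]
) -> None:
    required = ["subject_id", "timepoint", *scale.item_labels]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing columns: {missing_cols}")

    bad_tp = set(df["timepoint"]) - set(timepoints)
    if bad_tp:
        raise CohortValidationError(f"unknown timepoints: {sorted(bad_tp)}")

    dup = df.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise CohortValidationError(
            "duplicate record for subject "
            f"{first['subject_id']!r} at {first['timepoint']!r}"
        )

    for item in scale.item_labels:
        col = pd.to_numeric(df[item], errors="coerce")
        present = col.notna() & df[item].notna()
        values = col[present]
        if ((values % 1) != 0).any():
            bad = df.loc[values[(values % 1) != 0].index[0], "subject_id"]
            raise CohortValidationError(
                f"non-integer score in item {item!r} (subject {bad!r})"
            )
        out = (values < scale.item_min) | (values > scale.item_max)
        if out.any():
            bad = df.loc[values[out].index[0], "subject_id"]
            raise CohortValidationError(
                f"score out of range [{scale.item_min}, {scale.item_max}] "
                f"in item {item!r} (subject {bad!r})"
            )


def load_cohort(
    source: str | Path | io.IOBase,
    layout: str = "wide",
    scale: ScaleDefinition = KEDS,
    timepoints: Sequence[str] = TIMEPOINTS,
) -> CohortTable:
    """Read a cohort from delimited text.

    ``layout="wide"`` expects ``subject_id,timepoint,<item columns>``;
    ``layout="long"`` expects ``subject_id,timepoint,item,score`` and is
    pivoted to wide.  Missing scores may be empty fields or ``NA``.
    """
    try:
        df = pd.read_csv(source, na_values=["NA"], sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - surface the parser's row context
        raise CohortValidationError(f"could not parse cohort source: {exc}") from exc

    if layout == "long":
        expected = {"subject_id", "timepoint", "item", "score"}
        if not expected.issubset(df.columns):
            raise CohortValidationError(
                f"long layout requires columns {sorted(expected)}"
            )
        df = (
            df.pivot(index=["subject_id", "timepoint"], columns="item", values="score")
            .reset_index()
            .rename_axis(columns=None)
        )
    elif layout != "wide":
        raise ValueError("layout must be 'wide' or 'long'")

    return CohortTable(
        data=df.reset_index(drop=True), scale=scale, timepoints=tuple(timepoints)
    )


def total_score(responses: Sequence[float], scale: ScaleDefinition = KEDS) -> float:
    """Sum of the item scores; NaN when any item is missing.

    Totals with partial missingness are treated as missing rather than
    prorated, consistent with complete-case analysis.
    """
    arr = np.asarray(responses, dtype=float)
    if arr.shape != (scale.n_items,):
        raise ValueError(f"expected {scale.n_items} responses")
    if np.isnan(arr).any():
        return float("nan")
    return float(arr.sum())


def total_scores(cohort: CohortTable, timepoint: str) -> pd.Series:
    """Per-subject totals at one wave, indexed by subject_id (NaN-propagating)."""
    sub = cohort.at_timepoint(timepoint)
    items = sub[list(cohort.scale.item_labels)].astype(float)
    totals = items.sum(axis=1).where(~items.isna().any(axis=1))
    return pd.Series(totals.values, index=sub["subject_id"].values, name=timepoint)


class EmptyMatrixError(ValueError):
    """No complete cases remain at the requested timepoint."""


def complete_cases(cohort: CohortTable, timepoint: str) -> TimepointMatrix:
    """Subjects with all items present at one wave, in input row order."""
    sub = cohort.at_timepoint(timepoint)
    items = sub[list(cohort.scale.item_labels)].astype(float)
    keep = ~items.isna().any(axis=1)
    if not keep.any():
        raise EmptyMatrixError(f"no complete cases at {timepoint!r}")
    kept = sub[keep]
    logger.info(
        "complete cases at %s: %d of %d records", timepoint, keep.sum(), len(sub)
    )
    return TimepointMatrix(
        values=kept[list(cohort.scale.item_labels)].to_numpy(dtype=np.int64),
        subject_ids=kept["subject_id"].to_numpy(),
        timepoint=timepoint,
        scale=cohort.scale,
    )


def cronbach_alpha(matrix: TimepointMatrix | np.ndarray) -> float:
    """Cronbach's alpha: internal consistency of the item set.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(totals)),
    with sample (n-1) variances.  Accepts a complete-case matrix or any
    subjects-by-items array.
    """
    values = matrix.values if isinstance(matrix, TimepointMatrix) else matrix
    x = np.asarray(values, dtype=float)
    k = x.shape[1]
    if k < 2 or x.shape[0] < 3:
        raise ValueError("alpha requires >= 2 items and >= 3 subjects")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: zero total-score variance")
    item_vars = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Per-wave item means/SDs, complete-case total mean/SD, and missingness.

    One row per wave present in the cohort.  "Missing" counts subjects of
    the cohort without a complete record at that wave; the percentage is
    rounded half-up to an integer for display.
    """
    n_all = cohort.n_subjects
    rows = []
    for tp in cohort.present_timepoints():
        sub = cohort.at_timepoint(tp)
        items = sub[list(cohort.scale.item_labels)].astype(float)
        complete = ~items.isna().any(axis=1)
        totals = items[complete].sum(axis=1)
        n_complete = int(complete.sum())
        row: dict[str, object] = {"timepoint": tp, "n_complete": n_complete}
        for item in cohort.scale.item_labels:
            row[f"{item}_mean"] = items[item].mean()
            row[f"{item}_sd"] = items[item].std(ddof=1)
        row["total_mean"] = totals.mean() if n_complete else float("nan")
        row["total_sd"] = totals.std(ddof=1) if n_complete > 1 else float("nan")
        n_missing = n_all - n_complete
        row["missing_n"] = n_missing
        row["missing_pct"] = _round_half_up(100.0 * n_missing / n_all)
        rows.append(row)
    return pd.DataFrame(rows)
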