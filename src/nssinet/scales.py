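"""Instrument definitions, response-table I/O, scoring and descriptives.

Three self-report instruments are modelled:

* GAD-7 — 7 anxiety items, each scored 0-3; total 0-21.
* PHQ-9 — 9 depression items, each scored 0-3; total 0-27.
* ANSSIAQ — an adolescent non-suicidal self-injury (NSSI) questionnaire with
  a 19-item function subscale (F1-F19, 1-5 anchors) and a 12-item behavior
  subscale (NB1-NB12) split into factor B1 (self-injury without obvious
  tissue injury) and factor B2 (with obvious tissue injury).

Raw data arrive as a participant x item CSV; validation drops rows with
missing or out-of-range values (listwise deletion) and keeps count so the
retention rate can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScaleDefinition",
    "ResponseTable",
    "GAD7",
    "PHQ9",
    "ANSSIAQ_FUNCTION",
    "ANSSIAQ_BEHAVIOR",
    "DEFAULT_SCALES",
    "DEMOGRAPHIC_COLUMNS",
    "load_responses",
    "validate_responses",
    "score_scale",
    "describe",
    "descriptive_table",
]

DEMOGRAPHIC_COLUMNS = ("age", "sex", "education")


@dataclass(frozen=True)
class ScaleDefinition:
    """An instrument (or subscale): ordered items with shared response bounds.

    ``factors`` optionally partitions the items into named factor sums
    (used by the ANSSIAQ behavior subscale's B1/B2 split).
    """

    scale_id: str
    item_ids: tuple[str, ...]
    response_min: int
    response_max: int
    factors: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError(f"{self.scale_id}: duplicate item ids")
        if not self.response_min < self.response_max:
            raise ValueError(f"{self.scale_id}: response_min must be < response_max")
        if self.factors is not None:
            covered = [i for items in self.factors.values() for i in items]
            if sorted(covered) != sorted(self.item_ids):
                raise ValueError(
                    f"{self.scale_id}: factors must partition item_ids exactly"
                )

    @property
    def n_items(self) -> int:
        return len(self.item_ids)


GAD7 = ScaleDefinition("GAD7", tuple(f"GAD{i}" for i in range(1, 8)), 0, 3)
PHQ9 = ScaleDefinition("PHQ9", tuple(f"PHQ{i}" for i in range(1, 10)), 0, 3)
ANSSIAQ_FUNCTION = ScaleDefinition(
    "ANSSIAQ_FUNCTION", tuple(f"F{i}" for i in range(1, 20)), 1, 5
)
# Behavior anchors are frequency-style 0-5; factor B1 = no obvious tissue
# injury (items NB1-NB6), B2 = obvious tissue injury (NB7-NB12).
ANSSIAQ_BEHAVIOR = ScaleDefinition(
    "ANSSIAQ_BEHAVIOR",
    tuple(f"NB{i}" for i in range(1, 13)),
    0,
    5,
    factors={
        "B1": tuple(f"NB{i}" for i in range(1, 7)),
        "B2": tuple(f"NB{i}" for i in range(7, 13)),
    },
)

DEFAULT_SCALES: tuple[ScaleDefinition, ...] = (
    GAD7,
    PHQ9,
    ANSSIAQ_FUNCTION,
    ANSSIAQ_BEHAVIOR,
)


@dataclass
class ResponseTable:
    """Validated participant x item integer responses plus scale metadata."""

    values: pd.DataFrame
    scales: tuple[ScaleDefinition, ...]
    demographics: pd.DataFrame | None = None
    n_input: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.n_input == 0:
            self.n_input = len(self.values)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def items(self) -> list[str]:
        return list(self.values.columns)

    @property
    def retention(self) -> float:
        """Percentage of input rows retained after validation."""
        if self.n_input == 0:
            return 0.0
        return 100.0 * self.n / self.n_input

    def scale_for_item(self, item: str) -> ScaleDefinition:
        for sc in self.scales:
            if item in sc.item_ids:
                return sc
        raise KeyError(f"item {item!r} belongs to no known scale")

    def to_csv(self, path: str | Path) -> None:
        out = self.values
        if self.demographics is not None:
            out = pd.concat([self.demographics, self.values], axis=1)
        out.to_csv(path, index=False)


def _bounds_frame(
    values: pd.DataFrame, scales: Sequence[ScaleDefinition]
) -> tuple[pd.Series, pd.Series]:
    lo, hi = {}, {}
    item_to_scale: dict[str, ScaleDefinition] = {}
    for sc in scales:
        for item in sc.item_ids:
            if item in item_to_scale:
                raise ValueError(f"item {item!r} appears in more than one scale")
            item_to_scale[item] = sc
    for col in values.columns:
        if col not in item_to_scale:
            raise ValueError(f"unknown item column {col!r}")
        lo[col] = item_to_scale[col].response_min
        hi[col] = item_to_scale[col].response_max
    return pd.Series(lo), pd.Series(hi)


def validate_responses(
    frame: pd.DataFrame, scales: Sequence[ScaleDefinition]
) -> ResponseTable:
    """Validate a raw frame: split off demographics, drop bad rows, count them.

    A row is dropped if any item value is missing, non-numeric, or outside
    its item's declared response bounds ("outliers").
    """
    demo_cols = [c for c in frame.columns if c in DEMOGRAPHIC_COLUMNS]
    items = frame.drop(columns=demo_cols)
    if items.shape[1] == 0:
        raise ValueError("no item columns found")
    lo, hi = _bounds_frame(items, scales)

    numeric = items.apply(pd.to_numeric, errors="coerce")
    in_range = numeric.ge(lo, axis=1) & numeric.le(hi, axis=1)
    is_integral = numeric.eq(numeric.round())
    ok = (numeric.notna() & in_range & is_integral).all(axis=1)

    n_input = len(frame)
    kept = numeric.loc[ok].astype(int).reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("all rows dropped during validation")
    demo = None
    if demo_cols:
        demo = frame.loc[ok, demo_cols].reset_index(drop=True)
    used_scales = tuple(
        sc for sc in scales if any(i in kept.columns for i in sc.item_ids)
    )
    return ResponseTable(
        values=kept,
        scales=used_scales,
        demographics=demo,
        n_input=n_input,
        n_dropped=n_input - len(kept),
    )


def load_responses(
    path: str | Path, scales: Sequence[ScaleDefinition] = DEFAULT_SCALES
) -> ResponseTable:
    """Read a response CSV (header = item labels) and validate it."""
    frame = pd.read_csv(path)
    return validate_responses(frame, scales)


def score_scale(table: ResponseTable, scale: ScaleDefinition) -> pd.DataFrame:
    """Per-participant total (sum of items), plus factor sums if defined."""
    missing = [i for i in scale.item_ids if i not in table.values.columns]
    if missing:
        raise ValueError(f"{scale.scale_id}: missing items {missing}")
    out = pd.DataFrame(index=table.values.index)
    out["total"] = table.values[list(scale.item_ids)].sum(axis=1)
    if scale.factors is not None:
        for name, items in scale.factors.items():
            out[name] = table.values[list(items)].sum(axis=1)
    return out


def describe(values: Sequence[float] | np.ndarray | pd.Series) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of a numeric vector."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("describe expects a 1-d vector")
    if arr.size < 2:
        raise ValueError("sample SD undefined for fewer than 2 observations")
    return float(arr.mean()), float(arr.std(ddof=1))


def descriptive_table(table: ResponseTable) -> pd.DataFrame:
    """Cohort descriptives: demographics, scale/factor totals, function items.

    Returns columns ``variable, mean, sd, n`` (the shape of a
    "Mean +/- SD" summary table).  The sex column, if present, is summarised
    separately by :func:`sex_split`.
    """
    rows: list[tuple[str, float, float, int]] = []
    n = table.n
    if table.demographics is not None:
        for col in table.demographics.columns:
            vec = pd.to_numeric(table.demographics[col], errors="coerce")
            if vec.notna().all():
                m, s = describe(vec.to_numpy())
                rows.append((col, m, s, n))
    for sc in table.scales:
        scored = score_scale(table, sc)
        m, s = describe(scored["total"].to_numpy())
        rows.append((sc.scale_id, m, s, n))
        for fac in scored.columns.drop("total"):
            m, s = describe(scored[fac].to_numpy())
            rows.append((f"{sc.scale_id}:{fac}", m, s, n))
        if sc.scale_id == "ANSSIAQ_FUNCTION":
            for item in sc.item_ids:
                m, s = describe(table.values[item].to_numpy())
                rows.append((item, m, s, n))
    return pd.DataFrame(rows, columns=["variable", "mean", "sd", "n"])


def sex_split(table: ResponseTable) -> dict[str, float]:
    """Counts and percentage split of the sex column (M/F)."""
    if table.demographics is None or "sex" not in table.demographics.columns:
        raise ValueError("no sex column available")
    sex = table.demographics["sex"].astype(str)
    n_m = int((sex == "M").sum())
    n_f = int((sex == "F").sum())
    total = len(sex)
    return {
        "M": n_m,
        "F": n_f,
        "pct_female": round(100.0 * n_f / total, 2),
    }
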