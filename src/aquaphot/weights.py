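"""Weight-loss monitoring statistics.

Weight loss rate relative to the fresh (pre-storage) weight,
``(W_f - W_s) / W_f * 100`` in percent, day-to-day weight change in grams,
and the pooled-variance two-sample t-test used to compare the two cooling
conditions (a paired variant is provided for day-wise pairing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    GapError,
    InsufficientDataError,
    MissingBaselineError,
    SchemaError,
    UndefinedForBaselineError,
)

WEIGHT_COLUMNS = ("fruit_id", "condition", "day", "weight_g")


@dataclass
class WeightTable:
    """Per-fruit daily weights (grams), one record per (fruit, condition, day)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"weight table missing column(s): {missing}")
        if df.duplicated(subset=["fruit_id", "condition", "day"]).any():
            raise SchemaError("duplicate (fruit_id, condition, day) weight record")
        if (df["weight_g"] <= 0).any():
            raise SchemaError("weights must be strictly positive")
        if (df["day"] < 0).any():
            raise SchemaError("storage days are non-negative")
        self.records = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "WeightTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False, float_format="%.17g")

    def lookup(self, fruit_id, condition, day) -> float | None:
        df = self.records
        hit = df[
            (df["fruit_id"] == fruit_id)
            & (df["condition"] == condition)
            & (df["day"] == day)
        ]
        if hit.empty:
            return None
        return float(hit["weight_g"].iloc[0])

    def fruits(self, condition) -> list:
        df = self.records
        return sorted(df.loc[df["condition"] == condition, "fruit_id"].unique())


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def weight_loss_rate(table: WeightTable, fruit_id, condition, day) -> float:
    """Percent weight loss relative to the fresh weight (day 0).

    A negative return value (apparent weight gain) is reported with a warning
    rather than an error, since balance noise can produce it.
    """
    w_fresh = table.lookup(fruit_id, condition, 0)
    if w_fresh is None:
        raise MissingBaselineError(
            f"no day-0 record for fruit {fruit_id!r} in {condition}"
        )
    w_day = table.lookup(fruit_id, condition, day)
    if w_day is None:
        raise MissingBaselineError(
            f"no day-{day} record for fruit {fruit_id!r} in {condition}"
        )
    rate = (w_fresh - w_day) / w_fresh * 100.0
    if rate < 0:
        warnings.warn(
            f"fruit {fruit_id!r} gained weight by day {day} ({rate:.2f}%)",
            stacklevel=2,
        )
    return rate


def loss_rates(table: WeightTable, condition, day) -> pd.Series:
    """Weight-loss rates (percent) of every fruit of a condition at one day."""
    vals = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fruit in table.fruits(condition):
            vals[fruit] = weight_loss_rate(table, fruit, condition, day)
    return pd.Series(vals, name=f"loss_pct_{condition}_day{day}")


def daily_weight_change(table: WeightTable, fruit_id, condition, day) -> float:
    """Weight difference in grams versus the previous day (negative = loss)."""
    if day == 0:
        raise UndefinedForBaselineError("daily change is undefined at day 0")
    prev = table.lookup(fruit_id, condition, day - 1)
    if prev is None:
        raise GapError(f"no day-{day - 1} record for fruit {fruit_id!r}")
    cur = table.lookup(fruit_id, condition, day)
    if cur is None:
        raise GapError(f"no day-{day} record for fruit {fruit_id!r}")
    return cur - prev


def equal_variance_ttest(a, b) -> TTestResult:
    """Two-sample t-test with pooled variance (equal variances assumed).

    Returns the t statistic, ``df = n_a + n_b - 2`` and the two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(res.statistic), int(a.size + b.size - 2), float(res.pvalue))


def paired_ttest(a, b) -> TTestResult:
    """Paired-samples t-test (element-wise pairing, df = n - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise InsufficientDataError("paired samples must have equal length")
    if a.size < 2:
        raise InsufficientDataError("need at least 2 pairs")
    res = stats.ttest_rel(a, b)
    return TTestResult(float(res.statistic), int(a.size - 1), float(res.pvalue))
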