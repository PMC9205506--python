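"""From raw participant records to a normalized design matrix and binary labels.

Average steps per day (ASPD) is the sum of step counts over valid wearable
recording days divided by the number of valid days. Participants are labeled
1 when their ASPD falls strictly below a step threshold (2500 steps/day for
the home-vs-community split, 5500 for the aerobic-guideline split) and 0
otherwise; the below-threshold group is the target class. Features with
excessive missingness are removed first, then participants with any missing
value among the retained features, and the design matrix is min-max scaled
to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "FilterReport",
    "ScalerState",
    "ClassDistribution",
    "compute_aspd",
    "aspd_from_long",
    "label_threshold",
    "filter_missing",
    "fit_minmax",
    "apply_minmax",
    "class_distribution",
]

FEATURE_KINDS = ("continuous", "ordinal", "categorical")


@dataclass
class FeatureTable:
    """A participant-by-feature matrix with per-feature kind and missing mask.

    ``data`` is a DataFrame indexed by participant id (unique), one column per
    feature (unique names). ``kinds`` maps feature name -> one of
    ``continuous`` / ``ordinal`` / ``categorical``; categorical and ordinal
    variables are stored as their integer codes, matching how such cohorts
    are usually coded (e.g. sex coded 0/1).
    """

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("participant ids must be unique")
        if self.data.columns.has_duplicates:
            raise ValueError("feature names must be unique")
        unknown = set(self.kinds) - set(self.data.columns)
        if unknown:
            raise ValueError(f"kinds given for unknown features: {sorted(unknown)}")
        bad = {k: v for k, v in self.kinds.items() if v not in FEATURE_KINDS}
        if bad:
            raise ValueError(f"unknown feature kinds: {bad}")

    @property
    def ids(self) -> pd.Index:
        return self.data.index

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def n_participants(self) -> int:
        return len(self.data)

    def subset(self, features: Sequence[str]) -> "FeatureTable":
        return FeatureTable(
            data=self.data[list(features)].copy(),
            kinds={f: self.kinds[f] for f in features if f in self.kinds},
        )


def compute_aspd(daily_steps: Iterable[tuple[int, float, bool]]) -> float:
    """Average steps per day over the valid recording days.

    ``daily_steps`` is a sequence of ``(day, count, valid)`` records; counts
    on invalid days are ignored entirely. Raises ``ValueError`` when no valid
    day exists, since the participant's activity cannot be summarized.
    """
    counts = [count for _day, count, valid in daily_steps if valid]
    if not counts:
        raise ValueError("no valid recording days: ASPD is undefined")
    return float(sum(counts)) / len(counts)


def aspd_from_long(steps: pd.DataFrame) -> pd.Series:
    """ASPD per participant from a long table (id, day, steps, valid)."""
    required = {"id", "day", "steps", "valid"}
    if not required.issubset(steps.columns):
        raise ValueError(f"long step table needs columns {sorted(required)}")
    valid = steps[steps["valid"].astype(bool)]
    missing = set(steps["id"].unique()) - set(valid["id"].unique())
    if missing:
        raise ValueError(f"participants with zero valid days: {sorted(missing)}")
    out = valid.groupby("id")["steps"].mean()
    out.name = "aspd"
    return out


def label_threshold(aspd, threshold: float):
    """Binary outcome: 1 iff ASPD is strictly below ``threshold``.

    Label 1 marks the below-threshold (target) class; a participant exactly
    at the threshold has met it and is labeled 0. Accepts a scalar or an
    array/Series; negative ASPD or a non-positive threshold is rejected.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    arr = np.asarray(aspd, dtype=float)
    if np.any(arr < 0):
        raise ValueError("ASPD cannot be negative")
    labels = (arr < threshold).astype(int)
    if isinstance(aspd, pd.Series):
        return pd.Series(labels, index=aspd.index, name="label")
    if np.isscalar(aspd) or arr.ndim == 0:
        return int(labels)
    return labels


@dataclass(frozen=True)
class FilterReport:
    dropped_features: tuple[str, ...]
    dropped_participants: tuple


def filter_missing(
    table: FeatureTable, max_missing_fraction: float = 0.05
) -> tuple[FeatureTable, FilterReport]:
    """Drop features with too much missingness, then incomplete participants.

    Features whose missing fraction strictly exceeds ``max_missing_fraction``
    (default 5%) are removed first; participants with any missing value among
    the retained features are removed second. The report lists both, in that
    order. The result contains no missing entries.
    """
    if not 0.0 <= max_missing_fraction < 1.0:
        raise ValueError(
            f"max_missing_fraction must be in [0,1), got {max_missing_fraction}"
        )
    frac = table.data.isna().mean(axis=0)
    dropped_features = tuple(frac.index[frac > max_missing_fraction])
    kept = table.data.drop(columns=list(dropped_features))
    row_bad = kept.isna().any(axis=1)
    dropped_participants = tuple(kept.index[row_bad])
    kept = kept.loc[~row_bad]
    if kept.empty or kept.shape[1] == 0:
        raise ValueError("filtering removed every participant or every feature")
    out = FeatureTable(
        data=kept,
        kinds={f: k for f, k in table.kinds.items() if f in kept.columns},
    )
    return out, FilterReport(dropped_features, dropped_participants)


@dataclass(frozen=True)
class ScalerState:
    """Per-feature min and max observed on the fitting rows."""

    mins: pd.Series
    maxs: pd.Series

    def __post_init__(self) -> None:
        if (self.maxs < self.mins).any():
            raise ValueError("max < min in scaler state")


def fit_minmax(table: FeatureTable, fit_rows: Sequence | None = None) -> ScalerState:
    """Record per-feature min/max on ``fit_rows`` (default: all rows)."""
    data = table.data if fit_rows is None else table.data.iloc[list(fit_rows)]
    if data.empty:
        raise ValueError("cannot fit a scaler on zero rows")
    if data.isna().any().any():
        raise ValueError("cannot fit a scaler with missing values present")
    return ScalerState(mins=data.min(axis=0), maxs=data.max(axis=0))


def apply_minmax(table: FeatureTable, state: ScalerState) -> FeatureTable:
    """Map each value to (x - min) / (max - min) with the fitted extrema.

    Values outside the fitted range (possible when the scaler was fitted on a
    training fold) are NOT clipped, preserving the shape of the distribution.
    A constant feature (max == min) maps to 0 everywhere.
    """
    span = (state.maxs - state.mins).replace(0.0, 1.0)
    scaled = (table.data - state.mins) / span
    return FeatureTable(data=scaled, kinds=dict(table.kinds))


class ClassDistribution(NamedTuple):
    count_1: int
    count_0: int
    fraction_1: float
    fraction_0: float


def class_distribution(labels) -> ClassDistribution:
    """Counts and fractions of the positive (1) and negative (0) classes."""
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("labels are empty")
    n1 = int((arr == 1).sum())
    n0 = int((arr == 0).sum())
    if n1 + n0 != arr.size:
        raise ValueError("labels must be 0/1")
    return ClassDistribution(n1, n0, n1 / arr.size, n0 / arr.size)
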