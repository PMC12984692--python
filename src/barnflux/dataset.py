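"""Model-ready feature matrices: hourly aggregation, feature groups,
min/max normalization and the 70:15:15 split.

Input variables are organised in four named groups, combined into the
ablation configurations of the input-variable study:

* ``climatic``        hour of day, indoor/outdoor temperature, humidity,
                      wind speed and wind direction (9 columns)
* ``activity``        Cow Lying Index and Cow Activity Index (2 columns)
* ``diet``            the 13 ration ingredient masses
* ``concentrations``  indoor/outdoor CO2 and target-gas concentrations
                      (4 columns; emission targets only)

Concentration targets are predicted from climate, activity and diet alone;
emission targets may additionally use the measured concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import DIET_COLUMNS

__all__ = [
    "AblationConfig",
    "MinMaxNormalizer",
    "SplitDataset",
    "CLIMATIC_COLUMNS",
    "ACTIVITY_COLUMNS",
    "feature_sets",
    "group_columns",
    "aggregate_hourly",
    "split_70_15_15",
]

log = logging.getLogger(__name__)

CLIMATIC_COLUMNS = ["hour", "T_in", "T_out", "RH_in", "RH_out",
                    "WS_in", "WS_out", "WD_in", "WD_out"]
ACTIVITY_COLUMNS = ["CLI", "CAI"]

TARGETS = ("NH3_concentration", "CH4_concentration", "NH3_emission", "CH4_emission")

#: Printed row labels of the concentration input-variable study (7 rows).
CONCENTRATION_CONFIGS: list[tuple[str, tuple[str, ...]]] = [
    ("Climatic variables", ("climatic",)),
    ("Animal activity", ("activity",)),
    ("Diet", ("diet",)),
    ("Climatic variables and animal activity", ("climatic", "activity")),
    ("Climatic variables and diet", ("climatic", "diet")),
    ("Diet and animal activity", ("diet", "activity")),
    ("Climatic variables, animal activity and diet", ("climatic", "activity", "diet")),
]

#: Printed row labels of the emission input-variable study (15 rows).
EMISSION_CONFIGS: list[tuple[str, tuple[str, ...]]] = [
    ("Concentrations", ("concentrations",)),
    ("Climatic variables", ("climatic",)),
    ("Animal activity", ("activity",)),
    ("Diet", ("diet",)),
    ("Concentrations and climatic variables", ("concentrations", "climatic")),
    ("Concentrations and animal activity", ("concentrations", "activity")),
    ("Concentrations and diet", ("concentrations", "diet")),
    ("Climatic variables and animal activity", ("climatic", "activity")),
    ("Climatic variables and diet", ("climatic", "diet")),
    ("Animal activity and diet", ("activity", "diet")),
    ("Concentrations, climatic variables and animal activity",
     ("concentrations", "climatic", "activity")),
    ("Concentrations, climatic variables and diet",
     ("concentrations", "climatic", "diet")),
    ("Concentrations, animal activity and diet",
     ("concentrations", "activity", "diet")),
    ("Climatic variables, animal activity and diet",
     ("climatic", "activity", "diet")),
    ("Concentrations, climatic variables, animal activity and diet",
     ("concentrations", "climatic", "activity", "diet")),
]


def group_columns(group: str, gas: str) -> list[str]:
    """Feature columns belonging to one input-variable group."""
    if group == "climatic":
        return list(CLIMATIC_COLUMNS)
    if group == "activity":
        return list(ACTIVITY_COLUMNS)
    if group == "diet":
        return list(DIET_COLUMNS)
    if group == "concentrations":
        return ["C_CO2_in", "C_CO2_out", f"C_{gas}_in", f"C_{gas}_out"]
    raise ValueError(f"unknown feature group {group!r}")


@dataclass(frozen=True)
class AblationConfig:
    """A named subset of input-variable groups for one prediction target."""

    name: str
    groups: tuple[str, ...]
    target: str

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if not self.groups:
            raise ValueError("groups must be non-empty")
        unknown = set(self.groups) - {"concentrations", "climatic", "activity", "diet"}
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}")
        if self.target.endswith("_concentration") and "concentrations" in self.groups:
            raise ValueError("concentration targets never use the concentrations group")

    @property
    def gas(self) -> str:
        return self.target.split("_")[0]

    @property
    def feature_columns(self) -> list[str]:
        cols: list[str] = []
        for g in self.groups:
            cols.extend(group_columns(g, self.gas))
        return cols

    @property
    def target_column(self) -> str:
        if self.target.endswith("_concentration"):
            return f"C_{self.gas}_in"
        return "Et"


def feature_sets(target: str) -> list[AblationConfig]:
    """Enumerate the input-variable study for one target.

    Returns the 7 concentration configurations or the 15 emission
    configurations, in printed row order.
    """
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
    rows = (CONCENTRATION_CONFIGS if target.endswith("_concentration")
            else EMISSION_CONFIGS)
    return [AblationConfig(name=n, groups=g, target=target) for n, g in rows]


class MinMaxNormalizer:
    """Per-feature min/max scaling onto [-1, 1], fitted on training rows only.

    Constant features (max == min on the training partition) are mapped to 0
    with a logged warning; inversion restores in-range data exactly.
    """

    def __init__(self, feature_range: tuple[float, float] = (-1.0, 1.0)) -> None:
        self.feature_range = feature_range
        self.data_min_: pd.Series | None = None
        self.data_max_: pd.Series | None = None

    @property
    def fitted(self) -> bool:
        return self.data_min_ is not None

    def fit(self, X: pd.DataFrame) -> "MinMaxNormalizer":
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        constant = self.data_max_ == self.data_min_
        if constant.any():
            log.warning(
                "constant features mapped to 0: %s", list(X.columns[constant])
            )
        return self

    def _check(self, X: pd.DataFrame) -> None:
        if not self.fitted:
            raise RuntimeError("normalizer must be fitted before use")
        missing = set(self.data_min_.index) - set(X.columns)
        if missing:
            raise KeyError(f"columns missing at transform time: {sorted(missing)}")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check(X)
        lo, hi = self.feature_range
        span = (self.data_max_ - self.data_min_).replace(0.0, np.nan)
        scaled = (X[self.data_min_.index] - self.data_min_) / span
        scaled = scaled * (hi - lo) + lo
        return scaled.fillna(0.5 * (lo + hi))

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check(X)
        lo, hi = self.feature_range
        span = self.data_max_ - self.data_min_
        return (X[self.data_min_.index] - lo) / (hi - lo) * span + self.data_min_

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)


@dataclass(frozen=True)
class SplitDataset:
    """Disjoint train/validation/test row indices (70:15:15 by default)."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("partitions overlap")


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    """Integer partition sizes by the largest-remainder rule.

    Leftover rows go to the partitions with the largest fractional parts;
    exact remainder ties are broken in partition order (training first).
    """
    exact = [n * r for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    leftover = n - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:leftover]:
        base[i] += 1
    return base


def split_70_15_15(
    n: int, seed: int, ratios: Sequence[float] = (0.70, 0.15, 0.15)
) -> SplitDataset:
    """Random 70:15:15 row split with largest-remainder size rounding.

    A seeded uniform permutation is cut into train/validation/test blocks;
    the same seed always yields the same partitions.
    """
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    if abs(sum(ratios) - 1.0) > 1e-9 or len(ratios) != 3:
        raise ValueError("ratios must be three fractions summing to 1")
    sizes = _largest_remainder(n, ratios)
    perm = np.random.default_rng(seed).permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    return SplitDataset(
        train=np.sort(perm[:a]),
        validation=np.sort(perm[a:b]),
        test=np.sort(perm[b:]),
        seed=seed,
    )


def _circular_mean_deg(values: np.ndarray) -> float:
    rad = np.deg2rad(np.asarray(values, dtype=float))
    mean = np.angle(np.exp(1j * rad).mean())
    deg = float(np.rad2deg(mean) % 360.0)
    return 0.0 if deg >= 360.0 else deg  # tiny negative angles round to 360.0


def aggregate_hourly(samples: pd.DataFrame, timestamp_col: str = "timestamp") -> pd.DataFrame:
    """Collapse sub-hourly samples to hourly records.

    Linear variables take the arithmetic mean within each clock hour; wind
    direction columns (``WD*``) take the circular mean; indoor gas
    sampling-point columns (``C_<gas>_in_<k>``) are first averaged across
    points into ``C_<gas>_in``.  Hours with no samples do not appear.
    """
    df = samples.copy()
    ts = pd.to_datetime(df[timestamp_col])
    df = df.drop(columns=[timestamp_col])

    # collapse indoor sampling points
    bases = {c.rsplit("_", 1)[0] for c in df.columns
             if "_in_" in c and c.rsplit("_", 1)[1].isdigit()}
    for base in sorted(bases):
        pts = [c for c in df.columns if c.startswith(base + "_") and c[len(base) + 1:].isdigit()]
        df[base] = df[pts].mean(axis=1)
        df = df.drop(columns=pts)

    hour = ts.dt.floor("h")
    agg = {c: (_circular_mean_deg if c.startswith("WD") else "mean") for c in df.columns}
    out = df.groupby(hour.values).agg(agg)
    out.index.name = "timestamp"
    return out


def drop_incomplete_rows(df: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    """Drop rows with missing values in ``columns``, logging the count."""
    cols = list(columns)
    keep = df[cols].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d rows with missing values", dropped)
    return df[keep]
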