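"""Behavioural indices from 15-minute scan-sampling counts.

Scan sampling records, at fixed intervals, how many cows are lying, standing,
walking or feeding.  Two hourly indices summarise the scans:

* Cow Lying Index (CLI): fraction of observed cows lying.
* Cow Activity Index (CAI): fraction engaged in active behaviours
  (standing, walking and, by default, feeding).

Under the partition assumption (every cow is in exactly one category)
CLI + CAI = 1 for every scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ScanObservation",
    "cow_lying_index",
    "cow_activity_index",
    "hourly_behaviour",
    "DEFAULT_ACTIVE_BEHAVIOURS",
]

DEFAULT_ACTIVE_BEHAVIOURS = ("standing", "walking", "feeding")


@dataclass(frozen=True)
class ScanObservation:
    """One 15-minute behavioural scan: per-behaviour cow counts."""

    timestamp: pd.Timestamp
    n_lying: int
    n_standing: int
    n_walking: int
    n_feeding: int

    def __post_init__(self) -> None:
        counts = (self.n_lying, self.n_standing, self.n_walking, self.n_feeding)
        if any(c < 0 for c in counts):
            raise ValueError(f"scan counts must be >= 0, got {counts}")
        if self.n_total < 1:
            raise ValueError("scan must observe at least one cow")

    @property
    def n_total(self) -> int:
        return self.n_lying + self.n_standing + self.n_walking + self.n_feeding


def cow_lying_index(scan: ScanObservation) -> float:
    """CLI = lying count / total observed, in [0, 1]."""
    return scan.n_lying / scan.n_total


def cow_activity_index(
    scan: ScanObservation,
    active: Sequence[str] = DEFAULT_ACTIVE_BEHAVIOURS,
) -> float:
    """CAI = active count / total observed, in [0, 1].

    ``active`` selects which behaviours count as activity; with the default
    set (standing, walking, feeding) CLI + CAI = 1.
    """
    n_active = sum(getattr(scan, f"n_{b}") for b in active)
    return n_active / scan.n_total


def hourly_behaviour(
    scans: Iterable[ScanObservation],
    active: Sequence[str] = DEFAULT_ACTIVE_BEHAVIOURS,
) -> pd.DataFrame:
    """Hourly mean CLI/CAI from a time-sorted sequence of scans.

    Returns a DataFrame indexed by the hour start (``timestamp`` floored to
    the hour) with columns ``CLI`` and ``CAI``, the arithmetic means of the
    per-scan indices within each clock hour.  Hours with no scans simply do
    not appear; when merging onto an hourly grid they surface as missing
    values, never as zeros.
    """
    scans = list(scans)
    if not scans:
        return pd.DataFrame(columns=["CLI", "CAI"])
    times = [s.timestamp for s in scans]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("scans must be sorted by timestamp")
    df = pd.DataFrame(
        {
            "hour": pd.DatetimeIndex(times).floor("h"),
            "CLI": [cow_lying_index(s) for s in scans],
            "CAI": [cow_activity_index(s, active) for s in scans],
        }
    )
    out = df.groupby("hour", sort=True).mean()
    out.index.name = "timestamp"
    return out


def scans_from_frame(df: pd.DataFrame) -> list[ScanObservation]:
    """Build scans from a table with timestamp and n_lying..n_feeding columns."""
    return [
        ScanObservation(
            timestamp=pd.Timestamp(row["timestamp"]),
            n_lying=int(row["n_lying"]),
            n_standing=int(row["n_standing"]),
            n_walking=int(row["n_walking"]),
            n_feeding=int(row["n_feeding"]),
        )
        for _, row in df.iterrows()
    ]
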