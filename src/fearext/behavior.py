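"""Freezing scoring and extinction-recall grouping.

A rat is scored as freezing when it shows no movement except respiration for
at least 2 s; the total qualifying immobile time is normalized to the duration
of the CS presentation.  Rats are split into successful / poor
extinction-recall groups by comparing each rat's freezing during the recall
test of the first extinction session (the leading CSs of the following
session) with the upper bound of the 99% t confidence interval of the group
mean: strictly below the bound = successful recall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import upper_conf_bound

__all__ = [
    "FreezingRecord",
    "RecallGroup",
    "score_freezing",
    "score_movement_table",
    "session_freezing_means",
    "recall_epoch_freezing",
    "assign_recall_groups",
]


@dataclass(frozen=True)
class FreezingRecord:
    rat_id: str
    session: str
    cs_index: int
    freezing_pct: float

    def __post_init__(self):
        if not 0.0 <= self.freezing_pct <= 100.0:
            raise ValueError("freezing_pct outside [0, 100]")


@dataclass(frozen=True)
class RecallGroup:
    rat_id: str
    group: str  # "successful" | "poor"
    threshold_pct: float


def score_freezing(immobile: Sequence[int], dt_s: float, cs_duration_s: float,
                   min_bout_s: float = 2.0) -> float:
    """Percent of the CS window spent in immobility bouts of >= ``min_bout_s``.

    ``immobile`` is a binary trace sampled every ``dt_s`` seconds starting at
    CS onset.  A maximal immobility run qualifies if its *total* length is at
    least ``min_bout_s``; only the part of each qualifying run inside the CS
    window ``[0, cs_duration_s)`` is counted.
    """
    trace = np.asarray(immobile)
    if trace.ndim != 1:
        raise ValueError("immobile trace must be 1-D")
    if not np.isin(trace, (0, 1)).all():
        raise ValueError("immobile trace must be binary")
    n_window = int(round(cs_duration_s / dt_s))
    if trace.size < n_window:
        raise ValueError("trace shorter than the CS window")
    # maximal runs of 1s over the full trace
    padded = np.concatenate([[0], trace, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    frozen = 0.0
    for s, e in zip(starts, ends):
        if (e - s) * dt_s >= min_bout_s:
            overlap = max(0, min(e, n_window) - s)
            frozen += overlap * dt_s
    return 100.0 * frozen / cs_duration_s


def score_movement_table(movement: pd.DataFrame, cs_duration_s: float = 30.0,
                         dt_s: float = 0.1, min_bout_s: float = 2.0) -> pd.DataFrame:
    """Score every (rat, session, CS) trace in a movement table.

    ``movement`` columns: rat_id, session, cs_index, t_s, immobile.  Returns a
    freezing table with columns rat_id, session, cs_index, freezing_pct.
    """
    rows = []
    for (rat, session, cs), grp in movement.groupby(
            ["rat_id", "session", "cs_index"], sort=False):
        trace = grp.sort_values("t_s")["immobile"].to_numpy()
        pct = score_freezing(trace, dt_s, cs_duration_s, min_bout_s)
        rows.append((rat, session, int(cs), pct))
    return pd.DataFrame(rows, columns=["rat_id", "session", "cs_index", "freezing_pct"])


def session_freezing_means(freezing: pd.DataFrame) -> pd.DataFrame:
    """Per-(rat, session) mean freezing over CSs."""
    return (freezing.groupby(["rat_id", "session"], sort=False)["freezing_pct"]
            .mean().reset_index())


def recall_epoch_freezing(freezing: pd.DataFrame, session: str,
                          retention_window: int = 5) -> pd.Series:
    """Per-rat mean freezing over the leading ``retention_window`` CSs of a session.

    The leading CSs of each session probe recall of the previous session's
    learning; e.g. the first 5 CSs of the second extinction session measure
    extinction recall (post-Ext1).
    """
    sel = freezing[(freezing["session"] == session)
                   & (freezing["cs_index"] < retention_window)]
    if sel.empty:
        raise ValueError(f"no freezing records for session {session!r}")
    return sel.groupby("rat_id", sort=False)["freezing_pct"].mean()


def assign_recall_groups(post_ext1: Mapping[str, float] | pd.Series,
                         level: float = 0.99) -> tuple[list[RecallGroup], float]:
    """Split rats by the upper bound of the two-sided ``level`` t-interval.

    A rat with post-Ext1 freezing strictly below the bound is a successful
    extinction-recall rat; ties and values above are poor recall.
    """
    items = list(post_ext1.items())
    if len(items) < 2:
        raise ValueError("need >= 2 rats to form a confidence interval")
    values = np.array([v for _, v in items], dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite freezing values")
    threshold = upper_conf_bound(values, level=level)
    groups = [RecallGroup(rat, "successful" if v < threshold else "poor", threshold)
              for rat, v in items]
    return groups, threshold
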