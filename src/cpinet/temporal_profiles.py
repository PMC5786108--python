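"""Hourly CPI-frequency profiles: per-day counts, day-type distributions,
per-pair-type medians, and a cyclic smoother for 24-h curves.

"Hourly frequency" counts raw 30-s packets per clock hour (``[h:00, h+1:00)``),
not episodes.  Quantiles use linear interpolation (type-7).
"""

from __future__ import annotations

import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_cpi import drop_gap_records
from .types import DAY_S, GapSchedule, Roster, dates_of

PAIR_TYPES = ("all", "patient_patient", "staff_patient", "staff_staff")


def _pair_type(status_a: pd.Series, status_b: pd.Series) -> pd.Series:
    both_pat = (status_a == "patient") & (status_b == "patient")
    both_staff = (status_a == "staff") & (status_b == "staff")
    out = pd.Series("staff_patient", index=status_a.index)
    out[both_pat] = "patient_patient"
    out[both_staff] = "staff_staff"
    return out


def _normalize_week(week) -> tuple[int, int]:
    """Accept (year, week) tuples or ISO strings like '2009-W32'."""
    if isinstance(week, str):
        year, w = week.upper().split("-W")
        return int(year), int(w)
    year, w = week
    return int(year), int(w)


def hourly_counts(
    records: pd.DataFrame,
    roster: Roster,
    gaps: GapSchedule,
    epoch: datetime.date,
    exclusion_weeks: Iterable = (),
) -> pd.DataFrame:
    """Packet counts per (date, hour, pair type), zero-filled over the full
    observed date range.

    Dates inside gap intervals or in the excluded ISO weeks contribute no
    rows at all.  Columns: ``date, hour, day_type, pair_type, n_records``.
    """
    excluded = {_normalize_week(w) for w in exclusion_weeks}
    records = drop_gap_records(records, gaps, epoch)
    if records.empty:
        return pd.DataFrame(columns=["date", "hour", "day_type", "pair_type", "n_records"])
    df = records.copy()
    df["date"] = dates_of(df["t"], epoch)
    df["hour"] = (df["t"] % DAY_S) // 3600
    statuses = roster.status_map()
    df["pair_type"] = _pair_type(df["id_a"].map(statuses), df["id_b"].map(statuses))

    all_dates = pd.date_range(df["date"].min(), df["date"].max(), freq="D")
    keep_dates = [
        d
        for d in all_dates
        if not gaps.contains(d.date())
        and (d.isocalendar().year, d.isocalendar().week) not in excluded
    ]
    df = df[df["date"].isin(keep_dates)]

    counts = df.groupby(["date", "hour", "pair_type"]).size()
    grid = pd.MultiIndex.from_product(
        [keep_dates, range(24), list(PAIR_TYPES[1:])], names=["date", "hour", "pair_type"]
    )
    typed = counts.reindex(grid, fill_value=0).reset_index(name="n_records")
    total = (
        typed.groupby(["date", "hour"], as_index=False)["n_records"]
        .sum()
        .assign(pair_type="all")
    )
    out = pd.concat([total, typed], ignore_index=True)
    out["day_type"] = np.where(out["date"].dt.dayofweek >= 5, "weekend", "weekday")
    return out[["date", "hour", "day_type", "pair_type", "n_records"]].sort_values(
        ["date", "hour", "pair_type"], kind="mergesort"
    ).reset_index(drop=True)


def hourly_distribution(
    counts: pd.DataFrame, day_type: str, pair_type: str = "all"
) -> pd.DataFrame:
    """Five-number summary per hour over days of the given type.

    Columns: ``hour, min, q1, median, q3, max, n_days``.  Empty subsets yield
    an empty frame.
    """
    sub = counts[(counts["day_type"] == day_type) & (counts["pair_type"] == pair_type)]
    rows = []
    for hour, grp in sub.groupby("hour"):
        v = grp["n_records"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
        rows.append(
            {
                "hour": int(hour),
                "min": float(v.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(v.max()),
                "n_days": len(v),
            }
        )
    return pd.DataFrame(rows, columns=["hour", "min", "q1", "median", "q3", "max", "n_days"])


def median_hourly_by_pairtype(counts: pd.DataFrame) -> pd.DataFrame:
    """Median over days of the hourly packet count, per pair type and hour."""
    sub = counts[counts["pair_type"] != "all"]
    out = (
        sub.groupby(["pair_type", "hour"])["n_records"]
        .median()
        .reset_index(name="median")
    )
    return out


def smooth_profile(values: Sequence[float], bandwidth: float) -> np.ndarray:
    """Cyclic kernel smoother for a 24-point hour-of-day series.

    Nadaraya-Watson with a Gaussian kernel on circular hour distance (hour 23
    adjacent to hour 0).  On this uniform circular grid the weight matrix is
    doubly stochastic, so constants and the series total are preserved
    exactly; ``bandwidth -> 0`` recovers the input.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (24,):
        raise ValueError("expected a 24-point series")
    if bandwidth <= 1e-8:
        return v.copy()
    idx = np.arange(24)
    diff = np.abs(idx[:, None] - idx[None, :])
    circ = np.minimum(diff, 24 - diff)
    w = np.exp(-0.5 * (circ / bandwidth) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    return w @ v
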