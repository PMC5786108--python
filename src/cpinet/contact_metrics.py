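"""Daily contact quantities from a canonical CPI stream.

Two daily quantities drive everything downstream:

* per individual, the number of **distinct** partners met during a calendar
  day (``n_distinct``);
* per pair, the **cumulative duration** of contact over a day
  (30 s per recorded packet).

Episodes (maximal packet runs per pair, with a configurable inter-packet
tolerance, split at midnight) are also assembled for episode-level outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import scipy.stats

from .types import DAY_S, PACKET_S, GapSchedule, Roster, dates_of

#: default inter-packet gap (s) that still continues an episode
DEFAULT_GAP_TOLERANCE_S = 60


def build_episodes(records: pd.DataFrame, gap_tolerance_s: int = DEFAULT_GAP_TOLERANCE_S) -> pd.DataFrame:
    """Merge per-pair packet runs into contact episodes.

    A new episode starts when the gap to the previous packet of the same pair
    exceeds ``gap_tolerance_s``, or at a midnight boundary.  Returns one row
    per episode with columns ``id_a, id_b, start, end, n_packets, duration_s``
    where ``duration_s = 30 x n_packets`` and ``end`` is the end of the last
    detection window.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["id_a", "id_b", "start", "end", "n_packets", "duration_s"]
        )
    df = records.sort_values(["id_a", "id_b", "t"], kind="mergesort").reset_index(drop=True)
    t = df["t"].to_numpy()
    same_pair = (df["id_a"] == df["id_a"].shift()) & (df["id_b"] == df["id_b"].shift())
    same_pair = same_pair.to_numpy()
    dt = np.diff(t, prepend=t[0] if len(t) else 0)
    same_day = (t // DAY_S) == np.roll(t // DAY_S, 1)
    new_episode = ~same_pair | (dt > gap_tolerance_s) | ~same_day
    new_episode[0] = True
    ep_id = np.cumsum(new_episode) - 1
    grouped = df.groupby(ep_id, sort=True)
    out = grouped.agg(
        id_a=("id_a", "first"),
        id_b=("id_b", "first"),
        start=("t", "first"),
        end=("t", "last"),
        n_packets=("t", "size"),
    )
    out["end"] = out["end"] + PACKET_S
    out["duration_s"] = out["n_packets"] * PACKET_S
    return out.reset_index(drop=True)


def pair_days(
    records: pd.DataFrame,
    gaps: GapSchedule,
    epoch: datetime.date,
    gap_tolerance_s: int = DEFAULT_GAP_TOLERANCE_S,
) -> pd.DataFrame:
    """One row per (pair, date) with at least one packet outside the gaps.

    Columns: ``id_a, id_b, date, n_packets, cum_duration_s, n_episodes`` with
    ``cum_duration_s = 30 x n_packets``.
    """
    from .io_cpi import drop_gap_records

    records = drop_gap_records(records, gaps, epoch)
    if records.empty:
        return pd.DataFrame(
            columns=["id_a", "id_b", "date", "n_packets", "cum_duration_s", "n_episodes"]
        )
    episodes = build_episodes(records, gap_tolerance_s)
    episodes["date"] = dates_of(episodes["start"], epoch)
    out = (
        episodes.groupby(["id_a", "id_b", "date"], sort=True)
        .agg(n_packets=("n_packets", "sum"), n_episodes=("n_packets", "size"))
        .reset_index()
    )
    out["cum_duration_s"] = out["n_packets"] * PACKET_S
    return out[["id_a", "id_b", "date", "n_packets", "cum_duration_s", "n_episodes"]]


def _directed_pair_days(pair_day_table: pd.DataFrame) -> pd.DataFrame:
    """Stack both orientations of each pair-day: columns id, partner, date, cum_duration_s."""
    a = pair_day_table.rename(columns={"id_a": "id", "id_b": "partner"})
    b = pair_day_table.rename(columns={"id_b": "id", "id_a": "partner"})
    cols = ["id", "partner", "date", "cum_duration_s"]
    return pd.concat([a[cols], b[cols]], ignore_index=True)


def person_days(
    records: pd.DataFrame,
    roster: Roster,
    gaps: GapSchedule,
    epoch: datetime.date,
    gap_tolerance_s: int = DEFAULT_GAP_TOLERANCE_S,
) -> pd.DataFrame:
    """One row per (roster individual, presence day) outside the gap intervals.

    ``n_distinct`` counts the day's distinct partners; ``total_duration_s``
    sums the day's pair durations.  Present days without any record yield
    zeros (they count in person-level averages).
    """
    pd_table = pair_days(records, gaps, epoch, gap_tolerance_s)
    directed = _directed_pair_days(pd_table)
    per = (
        directed.groupby(["id", "date"], sort=True)
        .agg(n_distinct=("partner", "nunique"), total_duration_s=("cum_duration_s", "sum"))
        .reset_index()
    )
    # full presence grid
    rows = []
    for ind in roster:
        days = pd.date_range(ind.present_from, ind.present_to, freq="D")
        rows.append(pd.DataFrame({"id": ind.id, "date": days}))
    grid = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["id", "date"])
    if len(grid):
        grid = grid.loc[~gaps.mask(grid["date"])].reset_index(drop=True)
    out = grid.merge(per, on=["id", "date"], how="left")
    out["n_distinct"] = out["n_distinct"].fillna(0).astype(np.int64)
    out["total_duration_s"] = out["total_duration_s"].fillna(0).astype(np.int64)
    out["present"] = True
    return out


@dataclasses.dataclass(frozen=True)
class CategorySummary:
    """Mean of a daily quantity over its averaging units, with a Student-t 95% CI."""

    category: str
    mean: float
    ci95: tuple[float, float]
    n: int
    unit: str


def _t_ci(values: np.ndarray) -> tuple[float, float]:
    n = len(values)
    m = float(np.mean(values))
    if n < 2:
        return (float("nan"), float("nan"))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        return (m, m)
    half = scipy.stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return (m - half, m + half)


def category_mean_distinct(
    person_day_table: pd.DataFrame,
    roster: Roster,
    grouping: str = "person_day",
) -> list[CategorySummary]:
    """Mean daily distinct partners per category.

    ``grouping='person_day'`` pools all person-days of the category;
    ``grouping='per_individual'`` first averages within each individual, then
    across individuals.
    """
    if person_day_table.empty:
        raise ValueError("person_days table is empty")
    if grouping not in ("person_day", "per_individual"):
        raise ValueError(f"unknown grouping {grouping!r}")
    df = person_day_table.copy()
    df["category"] = df["id"].map(roster.category_map())
    out = []
    for category, sub in df.groupby("category", sort=True):
        if grouping == "per_individual":
            values = sub.groupby("id")["n_distinct"].mean().to_numpy(dtype=float)
        else:
            values = sub["n_distinct"].to_numpy(dtype=float)
        if len(values) == 0:
            continue
        out.append(
            CategorySummary(
                category=str(category),
                mean=float(np.mean(values)),
                ci95=_t_ci(values),
                n=len(values),
                unit="person_day",
            )
        )
    return out


def category_pair_mean_duration(
    pair_day_table: pd.DataFrame, roster: Roster
) -> list[CategorySummary]:
    """Mean daily cumulative contact duration (minutes/day) per unordered category pair."""
    if pair_day_table.empty:
        raise ValueError("pair_days table is empty")
    df = pair_day_table.copy()
    cats = roster.category_map()
    ca = df["id_a"].map(cats)
    cb = df["id_b"].map(cats)
    df["pair_cat"] = [
        f"{a}-{b}" if a <= b else f"{b}-{a}" for a, b in zip(ca, cb)
    ]
    out = []
    for pair_cat, sub in df.groupby("pair_cat", sort=True):
        minutes = sub["cum_duration_s"].to_numpy(dtype=float) / 60.0
        out.append(
            CategorySummary(
                category=str(pair_cat),
                mean=float(np.mean(minutes)),
                ci95=_t_ci(minutes),
                n=len(minutes),
                unit="pair_day",
            )
        )
    return out


def summaries_to_frame(summaries: list[CategorySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": s.category,
                "mean": s.mean,
                "ci_lo": s.ci95[0],
                "ci_hi": s.ci95[1],
                "n": s.n,
                "unit": s.unit,
            }
            for s in summaries
        ]
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (report convention for percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def category_involvement_summary(
    total_records: int, involvement_counts: dict[str, int]
) -> dict[str, tuple[int, float]]:
    """Counts and percentages of records involving each category.

    A record involving members of two categories counts once toward each, so
    percentages need not sum to 100.  Percentages are rounded half-up to two
    decimals.
    """
    if total_records <= 0:
        raise ValueError("total record count must be positive")
    out = {}
    for category, count in involvement_counts.items():
        if count > total_records:
            raise ValueError(
                f"category {category!r} count {count} exceeds total {total_records}"
            )
        out[category] = (count, round_half_up(100.0 * count / total_records))
    return out


def involvement_counts(records: pd.DataFrame, roster: Roster) -> dict[str, int]:
    """Per-category involvement counts computed directly from a record stream."""
    cats = roster.category_map()
    ca = records["id_a"].map(cats)
    cb = records["id_b"].map(cats)
    out: dict[str, int] = {}
    for cat in sorted(set(cats.values())):
        out[cat] = int(((ca == cat) | (cb == cat)).sum())
    return out
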