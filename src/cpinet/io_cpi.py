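"""Reading, validation, canonicalization and writing of CPI streams, rosters and gap schedules.

A CPI (close-proximity interaction) record is one detection packet on a 30-s
grid between two sensors.  On-disk formats are plain delimited text:

* CPI file — CSV with header ``t,id_a,id_b`` or a whitespace-separated
  header-less ``t i j`` contact list (the SocioPatterns convention);
* roster — CSV ``id,status,category,ward,age,gender,reason,present_from,present_to[,pvs]``
  with ISO-8601 dates;
* gap schedule — CSV ``start_date,end_date``.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    PACKET_S,
    Category,
    GapSchedule,
    Gender,
    Individual,
    Reason,
    Roster,
    RosterError,
    Status,
    Ward,
    dates_of,
)

RECORD_COLUMNS = ["t", "id_a", "id_b"]


class CPIFormatError(ValueError):
    """Raised on a malformed CPI row; message carries the 1-based line number."""


@dataclasses.dataclass(frozen=True)
class CanonReport:
    """Bookkeeping from canonicalization of a raw packet table."""

    n_input_rows: int
    n_self_loops_dropped: int
    n_duplicates_collapsed: int
    n_off_grid_floored: int

    @property
    def n_records(self) -> int:
        return self.n_input_rows - self.n_self_loops_dropped - self.n_duplicates_collapsed

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.n_records} records "
            f"({self.n_self_loops_dropped} self-loop(s) dropped, "
            f"{self.n_duplicates_collapsed} duplicate(s) collapsed, "
            f"{self.n_off_grid_floored} off-grid time(s) floored)"
        )


def canonicalize_records(raw: pd.DataFrame, grid_s: int = PACKET_S) -> tuple[pd.DataFrame, CanonReport]:
    """Canonicalize a raw packet table.

    Times are floored to the ``grid_s`` grid, self-loops dropped, each pair
    ordered with the lexicographically smaller id first, duplicate
    ``(pair, t)`` rows (including mirrored sensor reports) collapsed to one,
    and the result sorted by ``(t, id_a, id_b)``.
    """
    n_input = len(raw)
    t = raw["t"].to_numpy(dtype=np.int64)
    if (t < 0).any():
        raise CPIFormatError("negative timestamps present")
    floored = (t // grid_s) * grid_s
    n_off_grid = int((floored != t).sum())

    id_a = raw["id_a"].astype(str).to_numpy()
    id_b = raw["id_b"].astype(str).to_numpy()
    keep = id_a != id_b
    n_self = int(n_input - keep.sum())

    lo = np.minimum(id_a[keep], id_b[keep])
    hi = np.maximum(id_a[keep], id_b[keep])
    df = pd.DataFrame({"t": floored[keep], "id_a": lo, "id_b": hi})
    before = len(df)
    df = df.drop_duplicates(subset=RECORD_COLUMNS)
    n_dup = before - len(df)
    df = df.sort_values(RECORD_COLUMNS, kind="mergesort").reset_index(drop=True)
    return df, CanonReport(n_input, n_self, n_dup, n_off_grid)


def _read_raw_cpi(path: Path, dialect: dict[str, str] | None) -> pd.DataFrame:
    dialect = dialect or {}
    tcol = dialect.get("t", "t")
    acol = dialect.get("id_a", "id_a")
    bcol = dialect.get("id_b", "id_b")
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype=str)
        header_lines = 1
    elif path.suffix.lower() == ".tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        header_lines = 1
    else:  # whitespace `t i j` contact list, no header
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=[tcol, acol, bcol], dtype=str
        )
        header_lines = 0
    missing = [c for c in (tcol, acol, bcol) if c not in df.columns]
    if missing:
        raise CPIFormatError(f"{path}: missing column(s) {missing}")
    df = df.rename(columns={tcol: "t", acol: "id_a", bcol: "id_b"})[RECORD_COLUMNS]
    t_num = pd.to_numeric(df["t"], errors="coerce")
    bad = t_num.isna() | df["id_a"].isna() | df["id_b"].isna()
    if bad.any():
        line = int(bad.idxmax()) + header_lines + 1
        raise CPIFormatError(f"{path}: malformed row at line {line}")
    df["t"] = t_num.astype(np.int64)
    return df


def read_cpi_records(
    path: str | Path, dialect: dict[str, str] | None = None
) -> tuple[pd.DataFrame, CanonReport]:
    """Read and canonicalize a CPI packet file.

    Parameters
    ----------
    path
        ``.csv``/``.tsv`` files are read with a header; any other extension is
        treated as a whitespace-separated header-less ``t i j`` list.
    dialect
        Optional map from the canonical field names (``t``, ``id_a``,
        ``id_b``) to the column names used in the file.

    Returns
    -------
    records, report
        Canonical sorted record table and the canonicalization report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return canonicalize_records(_read_raw_cpi(path, dialect))


def write_cpi_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write records as CSV (``.csv``) or whitespace ``t i j`` (other suffixes)."""
    path = Path(path)
    out = records[RECORD_COLUMNS]
    if path.suffix.lower() in (".csv", ".tsv"):
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        out.to_csv(path, index=False, sep=sep)
    else:
        out.to_csv(path, index=False, header=False, sep=" ")


# ---------------------------------------------------------------------------
# Roster I/O
# ---------------------------------------------------------------------------

_ROSTER_REQUIRED = [
    "id",
    "status",
    "category",
    "ward",
    "age",
    "gender",
    "reason",
    "present_from",
    "present_to",
]


def _parse_enum(enum_cls, value: str, field: str, row_id: str):
    try:
        return enum_cls(value)
    except ValueError:
        raise RosterError(
            f"row {row_id!r}: unknown {field} label {value!r} "
            f"(expected one of {[e.value for e in enum_cls]})"
        ) from None


def read_roster(path: str | Path) -> Roster:
    """Read a roster CSV into a validated :class:`Roster`."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _ROSTER_REQUIRED if c not in df.columns]
    if missing:
        raise RosterError(f"{path}: missing roster column(s) {missing}")
    individuals = []
    for row in df.itertuples(index=False):
        rid = str(row.id)
        status = _parse_enum(Status, row.status, "status", rid)
        category = _parse_enum(Category, row.category, "category", rid)
        ward = _parse_enum(Ward, row.ward, "ward", rid)
        age = None if _isna(row.age) else int(float(row.age))
        gender = None if _isna(row.gender) else _parse_enum(Gender, row.gender, "gender", rid)
        reason = None if _isna(row.reason) else _parse_enum(Reason, row.reason, "reason", rid)
        pvs = False
        if hasattr(row, "pvs") and not _isna(row.pvs):
            pvs = str(row.pvs).strip().lower() in ("1", "true", "yes")
        individuals.append(
            Individual(
                id=rid,
                status=status,
                category=category,
                ward=ward,
                present_from=_parse_date(row.present_from, rid),
                present_to=_parse_date(row.present_to, rid),
                age_years=age,
                gender=gender,
                reason=reason,
                pvs=pvs,
            )
        )
    return Roster(individuals)


def _isna(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        isinstance(value, str) and value.strip() == ""
    )


def _parse_date(value: str, row_id: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(str(value))
    except ValueError:
        raise RosterError(f"row {row_id!r}: bad ISO date {value!r}") from None


def write_roster(roster: Roster, path: str | Path) -> None:
    df = roster.to_frame()
    df["age"] = df["age"].astype("Int64")
    df["pvs"] = df["pvs"].astype(int)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gap-schedule I/O
# ---------------------------------------------------------------------------


def read_gaps(path: str | Path) -> GapSchedule:
    df = pd.read_csv(path, dtype=str)
    for col in ("start_date", "end_date"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing gap column {col!r}")
    pairs = [
        (_parse_date(r.start_date, "gap"), _parse_date(r.end_date, "gap"))
        for r in df.itertuples(index=False)
    ]
    return GapSchedule.from_pairs(pairs)


def write_gaps(gaps: GapSchedule, path: str | Path) -> None:
    pd.DataFrame(
        [(s.isoformat(), e.isoformat()) for s, e in gaps.gaps],
        columns=["start_date", "end_date"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dataset validation
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ValidationReport:
    """Violation counts for a (records, roster, gaps) triple; report-only."""

    n_records: int
    n_unknown_id: int
    n_outside_presence: int
    n_in_gap: int
    involvement: dict[str, int]

    @property
    def ok(self) -> bool:
        return self.n_unknown_id == 0 and self.n_outside_presence == 0 and self.n_in_gap == 0


def validate_dataset(
    records: pd.DataFrame,
    roster: Roster,
    gaps: GapSchedule,
    epoch: datetime.date,
) -> ValidationReport:
    """Count records with unknown ids, outside presence, or inside gap intervals.

    ``involvement`` counts each record once per distinct category among its
    two members (so a record may count toward two categories).
    """
    dates = dates_of(records["t"], epoch)
    known = set(roster.ids)
    a_known = records["id_a"].isin(known)
    b_known = records["id_b"].isin(known)
    n_unknown = int((~(a_known & b_known)).sum())

    frame = roster.to_frame().set_index("id")
    pf = pd.to_datetime(frame["present_from"])
    pt = pd.to_datetime(frame["present_to"])
    a_from = records["id_a"].map(pf)
    a_to = records["id_a"].map(pt)
    b_from = records["id_b"].map(pf)
    b_to = records["id_b"].map(pt)
    inside = (
        (dates >= a_from) & (dates <= a_to) & (dates >= b_from) & (dates <= b_to)
    )
    # Only judge presence for records whose ids are both known.
    n_outside = int(((~inside) & a_known & b_known).sum())

    n_in_gap = int(gaps.mask(dates).sum())

    cat = frame["category"]
    cat_a = records["id_a"].map(cat)
    cat_b = records["id_b"].map(cat)
    involvement: dict[str, int] = {}
    for c in Category:
        involved = (cat_a == c.value) | (cat_b == c.value)
        n = int(involved.sum())
        if n:
            involvement[c.value] = n
    return ValidationReport(len(records), n_unknown, n_outside, n_in_gap, involvement)


def drop_gap_records(
    records: pd.DataFrame, gaps: GapSchedule, epoch: datetime.date
) -> pd.DataFrame:
    """Return records falling outside every gap interval."""
    if not gaps.gaps:
        return records
    mask = gaps.mask(dates_of(records["t"], epoch))
    return records.loc[~mask].reset_index(drop=True)
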