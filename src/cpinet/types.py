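"""Domain types shared across the package: enums, individuals, rosters, gap schedules."""

from __future__ import annotations

import dataclasses
import datetime
import enum
from typing import Iterable, Iterator

import pandas as pd

#: Length of one detection window, in seconds.
PACKET_S = 30

#: Seconds per day.
DAY_S = 86400


class Status(str, enum.Enum):
    patient = "patient"
    staff = "staff"


class Category(str, enum.Enum):
    patient = "patient"
    HCW = "HCW"
    reeducation = "reeducation"
    AHS = "AHS"
    physician = "physician"
    hospital_porter = "hospital_porter"
    logistic = "logistic"
    # Present in rosters but excluded from the statistical analyses.
    administration = "administration"
    animation = "animation"


#: Staff categories retained by the risk analyses (administration/animation excluded).
ANALYSIS_STAFF_CATEGORIES = frozenset(
    {
        Category.HCW,
        Category.reeducation,
        Category.AHS,
        Category.physician,
        Category.hospital_porter,
        Category.logistic,
    }
)


class Ward(str, enum.Enum):
    W1 = "W1"
    W2 = "W2"
    W3 = "W3"
    W4 = "W4"
    W5 = "W5"
    W6_transversal = "W6_transversal"


class Gender(str, enum.Enum):
    F = "F"
    M = "M"


class Reason(str, enum.Enum):
    orthopaedic = "orthopaedic"
    geriatric = "geriatric"
    neurology = "neurology"
    nutrition = "nutrition"
    post_operative = "post_operative"


#: Patient age bands, closed-open except the last; labels match report tables.
AGE_BANDS = (
    (18, 30, "[18,30)"),
    (30, 40, "[30,40)"),
    (40, 50, "[40,50)"),
    (50, 60, "[50,60)"),
    (60, 70, "[60,70)"),
    (70, None, "[70+]"),
)

AGE_BAND_LABELS = tuple(label for _, _, label in AGE_BANDS)

DAY_OF_WEEK_LABELS = (
    "Monday",
    "Tuesday",
    "Wednesday",
    "Thursday",
    "Friday",
    "Saturday",
    "Sunday",
)


def age_band(age_years: int) -> str:
    """Map an age in years to its band label."""
    if age_years < 18:
        raise ValueError(f"age {age_years} below adult range")
    for lo, hi, label in AGE_BANDS:
        if hi is None or age_years < hi:
            return label
    raise AssertionError("unreachable")


class RosterError(ValueError):
    """Raised when a roster row violates the schema."""


@dataclasses.dataclass(frozen=True)
class Individual:
    """One study participant with identity, category, ward and presence interval."""

    id: str
    status: Status
    category: Category
    ward: Ward
    present_from: datetime.date
    present_to: datetime.date
    age_years: int | None = None
    gender: Gender | None = None
    reason: Reason | None = None
    pvs: bool = False

    def __post_init__(self) -> None:
        # accept plain strings for the enum fields
        coercions = (
            ("status", Status),
            ("category", Category),
            ("ward", Ward),
            ("gender", Gender),
            ("reason", Reason),
        )
        for field, enum_cls in coercions:
            value = getattr(self, field)
            if value is not None and not isinstance(value, enum_cls):
                try:
                    object.__setattr__(self, field, enum_cls(value))
                except ValueError:
                    raise RosterError(
                        f"{self.id}: unknown {field} label {value!r}"
                    ) from None
        if self.present_from > self.present_to:
            raise RosterError(
                f"{self.id}: present_from {self.present_from} after present_to {self.present_to}"
            )
        is_patient_cat = self.category is Category.patient
        if is_patient_cat != (self.status is Status.patient):
            raise RosterError(
                f"{self.id}: status {self.status.value!r} inconsistent with "
                f"category {self.category.value!r}"
            )
        if self.status is Status.patient:
            for field in ("age_years", "gender", "reason"):
                if getattr(self, field) is None:
                    raise RosterError(f"{self.id}: patient missing required field {field!r}")
        if self.pvs and self.status is not Status.patient:
            raise RosterError(f"{self.id}: pvs flag only applies to patients")

    @property
    def age_band(self) -> str | None:
        return None if self.age_years is None else age_band(self.age_years)


class Roster:
    """Collection of :class:`Individual`, keyed by id."""

    def __init__(self, individuals: Iterable[Individual]):
        self._by_id: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._by_id:
                raise RosterError(f"duplicate id {ind.id!r}")
            self._by_id[ind.id] = ind

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._by_id.values())

    def __contains__(self, id_: str) -> bool:
        return id_ in self._by_id

    def __getitem__(self, id_: str) -> Individual:
        return self._by_id[id_]

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def patients(self) -> list[Individual]:
        return [i for i in self if i.status is Status.patient]

    def staff(self) -> list[Individual]:
        return [i for i in self if i.status is Status.staff]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with enum values as strings and dates as ``datetime.date``."""
        rows = []
        for ind in self:
            rows.append(
                {
                    "id": ind.id,
                    "status": ind.status.value,
                    "category": ind.category.value,
                    "ward": ind.ward.value,
                    "age": ind.age_years,
                    "gender": None if ind.gender is None else ind.gender.value,
                    "reason": None if ind.reason is None else ind.reason.value,
                    "present_from": ind.present_from,
                    "present_to": ind.present_to,
                    "pvs": ind.pvs,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "id",
                "status",
                "category",
                "ward",
                "age",
                "gender",
                "reason",
                "present_from",
                "present_to",
                "pvs",
            ],
        )

    def category_map(self) -> dict[str, str]:
        return {i.id: i.category.value for i in self}

    def status_map(self) -> dict[str, str]:
        return {i.id: i.status.value for i in self}

    def ward_map(self) -> dict[str, str]:
        return {i.id: i.ward.value for i in self}


@dataclasses.dataclass(frozen=True)
class GapSchedule:
    """Closed date intervals during which recording is invalid (battery changes)."""

    gaps: tuple[tuple[datetime.date, datetime.date], ...] = ()

    def __post_init__(self) -> None:
        prev_end: datetime.date | None = None
        for start, end in self.gaps:
            if start > end:
                raise ValueError(f"gap interval {start}..{end} reversed")
            if prev_end is not None and start <= prev_end:
                raise ValueError("gap intervals must be sorted and non-overlapping")
            prev_end = end

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[datetime.date, datetime.date]]
    ) -> "GapSchedule":
        return cls(tuple(sorted(pairs)))

    def contains(self, day: datetime.date) -> bool:
        return any(start <= day <= end for start, end in self.gaps)

    def mask(self, dates: pd.Series) -> pd.Series:
        """Boolean mask (aligned with ``dates``) of entries falling inside a gap."""
        out = pd.Series(False, index=dates.index)
        for start, end in self.gaps:
            out |= (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
        return out

    @property
    def n_days(self) -> int:
        return sum((end - start).days + 1 for start, end in self.gaps)


def dates_of(t: pd.Series, epoch: datetime.date) -> pd.Series:
    """Calendar dates of packet timestamps ``t`` (seconds since ``epoch`` midnight)."""
    return pd.Timestamp(epoch) + pd.to_timedelta(t // DAY_S, unit="D")
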