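"""Synthetic LTCF roster and contact-stream generator.

Generates a multi-ward long-term care facility: a roster of patients with
exponential lengths of stay and ward-attached staff, and a CPI packet stream
in which pair episodes start according to an inhomogeneous Poisson process
(category-pair base rate x circadian hour weight x day-of-week multiplier x
within-ward boost) and run for a geometric number of consecutive 30-s packets.
Everything is driven by one integer seed, so identical configs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_cpi import canonicalize_records, drop_gap_records
from .types import (
    DAY_S,
    PACKET_S,
    AGE_BANDS,
    Category,
    GapSchedule,
    Gender,
    Individual,
    Reason,
    Roster,
    Status,
    Ward,
)

PairKey = tuple[str, str]


def pair_key(c1: str, c2: str) -> PairKey:
    """Canonical unordered category-pair key."""
    return (c1, c2) if c1 <= c2 else (c2, c1)


# -- default calibration ----------------------------------------------------
# Episode-initiation rates in episodes per pair-hour at circadian weight 1,
# for cross-ward pairs; within-ward pairs are boosted by ``same_ward_boost``.
# Chosen so the category ordering of mean daily distinct contacts is
# porter > physician > HCW > patient and patient-patient pair durations
# dominate HCW-patient ones.
DEFAULT_PAIR_RATES: dict[PairKey, float] = {
    pair_key("patient", "patient"): 0.00045,
    pair_key("patient", "HCW"): 0.0012,
    pair_key("patient", "physician"): 0.0021,
    pair_key("patient", "hospital_porter"): 0.0075,
    pair_key("patient", "reeducation"): 0.0011,
    pair_key("patient", "AHS"): 0.0009,
    pair_key("patient", "logistic"): 0.0004,
    pair_key("HCW", "HCW"): 0.0008,
    pair_key("HCW", "physician"): 0.0009,
    pair_key("HCW", "hospital_porter"): 0.0016,
    pair_key("HCW", "reeducation"): 0.0006,
    pair_key("HCW", "AHS"): 0.0006,
    pair_key("HCW", "logistic"): 0.0004,
    pair_key("physician", "physician"): 0.0012,
    pair_key("physician", "reeducation"): 0.0006,
    pair_key("physician", "AHS"): 0.0004,
    pair_key("physician", "hospital_porter"): 0.0012,
    pair_key("physician", "logistic"): 0.0003,
    pair_key("hospital_porter", "hospital_porter"): 0.0015,
    pair_key("hospital_porter", "reeducation"): 0.0008,
    pair_key("hospital_porter", "AHS"): 0.0008,
    pair_key("hospital_porter", "logistic"): 0.0012,
    pair_key("reeducation", "reeducation"): 0.0008,
    pair_key("reeducation", "AHS"): 0.0004,
    pair_key("reeducation", "logistic"): 0.0003,
    pair_key("AHS", "AHS"): 0.0006,
    pair_key("AHS", "logistic"): 0.0005,
    pair_key("logistic", "logistic"): 0.0006,
}

# Mean episode length in 30-s packets per category pair (patient-patient largest).
DEFAULT_DURATION_MEAN_PACKETS: dict[PairKey, float] = {
    pair_key("patient", "patient"): 110.0,
    pair_key("patient", "HCW"): 22.0,
    pair_key("patient", "physician"): 40.0,
    pair_key("patient", "reeducation"): 45.0,
    pair_key("patient", "hospital_porter"): 6.0,
    pair_key("patient", "AHS"): 12.0,
    pair_key("patient", "logistic"): 6.0,
}
DEFAULT_STAFF_STAFF_DURATION = 8.0

# Morning-peaked circadian weights (hour 0..23), normalized to mean 1.
_RAW_CIRCADIAN = np.array(
    [
        0.15, 0.12, 0.10, 0.10, 0.15, 0.45, 0.85, 1.40, 1.95, 2.30, 2.45, 2.30,
        1.65, 1.40, 1.50, 1.55, 1.45, 1.25, 1.30, 1.15, 0.80, 0.50, 0.30, 0.18,
    ]
)
DEFAULT_CIRCADIAN = tuple(_RAW_CIRCADIAN * 24.0 / _RAW_CIRCADIAN.sum())

#: Monday..Sunday multipliers on episode-initiation rate (weekend < weekday).
DEFAULT_DOW = (1.0, 1.0, 1.0, 1.05, 1.05, 0.60, 0.50)

DEFAULT_WARD_CENSUS: dict[str, dict[str, int]] = {
    "W1": {"patient": 28, "HCW": 20, "reeducation": 4, "AHS": 5, "physician": 2},
    "W2": {"patient": 28, "HCW": 20, "reeducation": 4, "AHS": 5, "physician": 2},
    "W3": {"patient": 27, "HCW": 20, "reeducation": 4, "AHS": 5, "physician": 2},
    "W4": {"patient": 27, "HCW": 20, "reeducation": 4, "AHS": 5, "physician": 2},
    "W5": {"patient": 26, "HCW": 20, "reeducation": 4, "AHS": 5, "physician": 2},
    "W6_transversal": {"hospital_porter": 5, "logistic": 8, "HCW": 4, "reeducation": 2},
}

# Ward specialties: W1/W2/W4 neurologic rehabilitation, W3 geriatric, W5 nutrition.
DEFAULT_REASON_DIST: dict[str, dict[str, float]] = {
    "W1": {"neurology": 0.70, "orthopaedic": 0.15, "post_operative": 0.15},
    "W2": {"neurology": 0.70, "orthopaedic": 0.15, "post_operative": 0.15},
    "W3": {"geriatric": 0.80, "orthopaedic": 0.10, "post_operative": 0.10},
    "W4": {"neurology": 0.70, "orthopaedic": 0.15, "post_operative": 0.15},
    "W5": {"nutrition": 0.85, "post_operative": 0.15},
}

# Per-ward probabilities over the six age bands.
DEFAULT_AGE_DIST: dict[str, Sequence[float]] = {
    "W1": (0.15, 0.15, 0.20, 0.20, 0.15, 0.15),
    "W2": (0.15, 0.15, 0.20, 0.20, 0.15, 0.15),
    "W3": (0.0, 0.0, 0.05, 0.15, 0.30, 0.50),
    "W4": (0.15, 0.15, 0.20, 0.20, 0.15, 0.15),
    "W5": (0.15, 0.20, 0.20, 0.20, 0.15, 0.10),
}


class SyntheticConfigError(ValueError):
    pass


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the synthetic hospital; defaults give a ~310-person, 5-ward LTCF."""

    n_days: int = 28
    epoch: datetime.date = datetime.date(2009, 7, 6)  # a Monday
    ward_census: dict[str, dict[str, int]] = dataclasses.field(
        default_factory=lambda: {w: dict(c) for w, c in DEFAULT_WARD_CENSUS.items()}
    )
    pair_rate: dict[PairKey, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PAIR_RATES)
    )
    circadian_weights: Sequence[float] = DEFAULT_CIRCADIAN
    dow_multipliers: Sequence[float] = DEFAULT_DOW
    same_ward_boost: float = 10.0
    cross_ward_patient_mult: float = 0.5
    duration_mean_packets: dict[PairKey, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_DURATION_MEAN_PACKETS)
    )
    default_duration_mean_packets: float = DEFAULT_STAFF_STAFF_DURATION
    weekend_duration_mult: float = 1.5
    stay_mean_days: float = 49.0
    gap_schedule: GapSchedule = dataclasses.field(default_factory=GapSchedule)
    planted_effects: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)
    pvs_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.circadian_weights = tuple(float(v) for v in self.circadian_weights)
        self.dow_multipliers = tuple(float(v) for v in self.dow_multipliers)
        if self.n_days <= 0:
            raise SyntheticConfigError("n_days must be positive")
        if len(self.circadian_weights) != 24:
            raise SyntheticConfigError("circadian_weights must have 24 entries")
        if len(self.dow_multipliers) != 7:
            raise SyntheticConfigError("dow_multipliers must have 7 entries")
        for name, values in (
            ("circadian_weights", self.circadian_weights),
            ("dow_multipliers", self.dow_multipliers),
        ):
            if any(v < 0 for v in values):
                raise SyntheticConfigError(f"{name} must be nonnegative")
        if any(r < 0 for r in self.pair_rate.values()):
            raise SyntheticConfigError("pair rates must be nonnegative")
        if any(m < 1 for m in self.duration_mean_packets.values()):
            raise SyntheticConfigError("duration means must be >= 1 packet")
        if self.same_ward_boost < 1:
            raise SyntheticConfigError("same_ward_boost must be >= 1")
        for ward, census in self.ward_census.items():
            Ward(ward)
            for cat, n in census.items():
                Category(cat)
                if n < 0:
                    raise SyntheticConfigError(f"negative census for {ward}/{cat}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_days": self.n_days,
            "epoch": self.epoch.isoformat(),
            "ward_census": self.ward_census,
            "pair_rate": {f"{a}|{b}": v for (a, b), v in self.pair_rate.items()},
            "circadian_weights": list(map(float, self.circadian_weights)),
            "dow_multipliers": list(map(float, self.dow_multipliers)),
            "same_ward_boost": self.same_ward_boost,
            "cross_ward_patient_mult": self.cross_ward_patient_mult,
            "duration_mean_packets": {
                f"{a}|{b}": v for (a, b), v in self.duration_mean_packets.items()
            },
            "default_duration_mean_packets": self.default_duration_mean_packets,
            "weekend_duration_mult": self.weekend_duration_mult,
            "stay_mean_days": self.stay_mean_days,
            "gaps": [[s.isoformat(), e.isoformat()] for s, e in self.gap_schedule.gaps],
            "planted_effects": self.planted_effects,
            "pvs_fraction": self.pvs_fraction,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        kwargs: dict = {}
        if "n_days" in d:
            kwargs["n_days"] = int(d["n_days"])
        if "epoch" in d:
            kwargs["epoch"] = datetime.date.fromisoformat(d["epoch"])
        if "ward_census" in d:
            kwargs["ward_census"] = {
                w: {c: int(n) for c, n in census.items()}
                for w, census in d["ward_census"].items()
            }
        if "pair_rate" in d:
            kwargs["pair_rate"] = {
                pair_key(*k.split("|")): float(v) for k, v in d["pair_rate"].items()
            }
        if "duration_mean_packets" in d:
            kwargs["duration_mean_packets"] = {
                pair_key(*k.split("|")): float(v)
                for k, v in d["duration_mean_packets"].items()
            }
        if "gaps" in d:
            kwargs["gap_schedule"] = GapSchedule.from_pairs(
                (datetime.date.fromisoformat(s), datetime.date.fromisoformat(e))
                for s, e in d["gaps"]
            )
        for key in (
            "circadian_weights",
            "dow_multipliers",
            "same_ward_boost",
            "cross_ward_patient_mult",
            "default_duration_mean_packets",
            "weekend_duration_mult",
            "stay_mean_days",
            "planted_effects",
            "pvs_fraction",
            "seed",
        ):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)


@dataclasses.dataclass
class SyntheticDataset:
    roster: Roster
    records: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# Roster generation
# ---------------------------------------------------------------------------


def draw_stay_lengths(n: int, mean_days: float, rng: np.random.Generator) -> np.ndarray:
    """Exponential stay lengths in whole days (>= 1)."""
    return np.maximum(1, np.ceil(rng.exponential(mean_days, size=n))).astype(np.int64)


def generate_roster(config: SyntheticConfig, rng_seed: int | None = None) -> Roster:
    """Draw a roster: ward-attached staff present the whole horizon, and
    per-bed chains of patients with exponential stays straddling the horizon."""
    if not config.ward_census:
        raise SyntheticConfigError("ward_census is empty")
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    start = config.epoch
    end = config.epoch + datetime.timedelta(days=config.n_days - 1)
    individuals: list[Individual] = []
    n_pat = 0
    n_staff = 0
    for ward_name in sorted(config.ward_census):
        census = config.ward_census[ward_name]
        ward = Ward(ward_name)
        reason_dist = DEFAULT_REASON_DIST.get(ward_name, {"neurology": 1.0})
        reason_labels = sorted(reason_dist)
        reason_p = np.array([reason_dist[r] for r in reason_labels])
        reason_p = reason_p / reason_p.sum()
        age_p = np.asarray(DEFAULT_AGE_DIST.get(ward_name, (1 / 6.0,) * 6))
        age_p = age_p / age_p.sum()
        for cat_name in sorted(census):
            n = census[cat_name]
            cat = Category(cat_name)
            if cat is Category.patient:
                # Each "bed" hosts a chain of successive patients.
                for _ in range(n):
                    burnin = int(3 * config.stay_mean_days)
                    day = -burnin + int(rng.integers(0, max(1, burnin // 2)))
                    while day < config.n_days:
                        stay = int(draw_stay_lengths(1, config.stay_mean_days, rng)[0])
                        s_day, e_day = day, day + stay - 1
                        day = e_day + 1 + int(rng.integers(0, 3))  # bed turnover gap
                        if e_day < 0 or s_day >= config.n_days:
                            continue
                        n_pat += 1
                        band = AGE_BANDS[rng.choice(6, p=age_p)]
                        lo, hi = band[0], band[1] if band[1] is not None else 95
                        individuals.append(
                            Individual(
                                id=f"P{n_pat:04d}",
                                status=Status.patient,
                                category=Category.patient,
                                ward=ward,
                                present_from=max(start, start + datetime.timedelta(days=s_day)),
                                present_to=min(end, start + datetime.timedelta(days=e_day)),
                                age_years=int(rng.integers(lo, hi)),
                                gender=Gender.M if rng.random() < 0.5 else Gender.F,
                                reason=Reason(reason_labels[rng.choice(len(reason_labels), p=reason_p)]),
                                pvs=bool(rng.random() < config.pvs_fraction),
                            )
                        )
            else:
                for _ in range(n):
                    n_staff += 1
                    individuals.append(
                        Individual(
                            id=f"S{n_staff:04d}",
                            status=Status.staff,
                            category=cat,
                            ward=ward,
                            present_from=start,
                            present_to=end,
                        )
                    )
    return Roster(individuals)


# ---------------------------------------------------------------------------
# Contact generation
# ---------------------------------------------------------------------------

_CATS = [c.value for c in Category]
_CAT_CODE = {c: i for i, c in enumerate(_CATS)}


def _rate_matrices(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    k = len(_CATS)
    rates = np.zeros((k, k))
    durs = np.full((k, k), config.default_duration_mean_packets)
    for (a, b), v in config.pair_rate.items():
        ia, ib = _CAT_CODE[a], _CAT_CODE[b]
        rates[ia, ib] = rates[ib, ia] = v
    for (a, b), v in config.duration_mean_packets.items():
        ia, ib = _CAT_CODE[a], _CAT_CODE[b]
        durs[ia, ib] = durs[ib, ia] = v
    return rates, durs


def plant_outcome_effects(config: SyntheticConfig, roster: Roster) -> pd.Series:
    """Per-person rate multipliers implementing ``config.planted_effects``.

    Effects are log-scale shifts keyed ``{covariate: {level: log_effect}}``;
    a person's multiplier is ``exp(sum of matching effects)``.  Supported
    covariates: ``category``, ``ward``, ``gender``, ``reason``.
    """
    valid = {"category", "ward", "gender", "reason"}
    for cov in config.planted_effects:
        if cov not in valid:
            raise SyntheticConfigError(
                f"planted effect on unknown covariate {cov!r} (expected one of {sorted(valid)})"
            )
    log_mod = pd.Series(0.0, index=pd.Index(roster.ids, name="id"))
    for cov, levels in config.planted_effects.items():
        for ind in roster:
            value = getattr(ind, cov if cov != "category" else "category")
            value = None if value is None else value.value
            if value in levels:
                log_mod[ind.id] += float(levels[value])
    return np.exp(log_mod)


def generate_contacts(
    config: SyntheticConfig,
    roster: Roster,
    rng_seed: int | None = None,
    rate_modifiers: pd.Series | None = None,
) -> pd.DataFrame:
    """Simulate the CPI packet stream for ``roster`` under ``config``.

    For every co-present eligible pair, daily episode counts are Poisson with
    mean ``pair_rate x sum(circadian weights) x dow multiplier x ward factor``;
    episode start hours follow the circadian weights, and each episode emits a
    geometric run of consecutive 30-s packets clipped at the day boundary.
    The output is canonical (sorted, deduplicated) and gap-filtered.
    """
    if len(roster) == 0:
        raise SyntheticConfigError("roster is empty")
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    frame = roster.to_frame()
    ids = frame["id"].to_numpy()
    cat = frame["category"].map(_CAT_CODE).to_numpy()
    ward = frame["ward"].to_numpy()
    is_patient = (frame["status"] == "patient").to_numpy()
    from_day = np.array([(d - config.epoch).days for d in frame["present_from"]])
    to_day = np.array([(d - config.epoch).days for d in frame["present_to"]])

    rates, durs = _rate_matrices(config)
    circ = np.asarray(config.circadian_weights, dtype=float)
    circ_sum = circ.sum()
    circ_p = circ / circ_sum if circ_sum > 0 else np.full(24, 1 / 24.0)
    dow_mult = np.asarray(config.dow_multipliers, dtype=float)
    if rate_modifiers is None:
        mod = np.ones(len(ids))
    else:
        mod = pd.Series(rate_modifiers).reindex(ids).fillna(1.0).to_numpy()

    chunks: list[pd.DataFrame] = []
    for day in range(config.n_days):
        date = config.epoch + datetime.timedelta(days=day)
        dow = date.weekday()
        if dow_mult[dow] == 0:
            continue
        present = np.flatnonzero((from_day <= day) & (to_day >= day))
        if len(present) < 2:
            continue
        ii, jj = np.triu_indices(len(present), k=1)
        pi, pj = present[ii], present[jj]
        lam = rates[cat[pi], cat[pj]] * circ_sum * dow_mult[dow] * mod[pi] * mod[pj]
        same_ward = ward[pi] == ward[pj]
        factor = np.where(same_ward, config.same_ward_boost, 1.0)
        both_pat = is_patient[pi] & is_patient[pj]
        factor = np.where(~same_ward & both_pat, config.cross_ward_patient_mult, factor)
        lam = lam * factor
        n_eps = rng.poisson(lam)
        active = np.flatnonzero(n_eps)
        if len(active) == 0:
            continue
        rep = np.repeat(active, n_eps[active])
        ep_i, ep_j = pi[rep], pj[rep]
        hours = rng.choice(24, size=len(rep), p=circ_p)
        slot = rng.integers(0, DAY_S // PACKET_S // 24, size=len(rep))
        start_t = day * DAY_S + hours * 3600 + slot * PACKET_S
        mean_pkts = durs[cat[ep_i], cat[ep_j]]
        if dow >= 5:
            mean_pkts = mean_pkts * config.weekend_duration_mult
        lengths = rng.geometric(1.0 / np.maximum(mean_pkts, 1.0))
        # clip runs at the end of the day
        max_len = (day + 1) * DAY_S - start_t
        lengths = np.minimum(lengths, max_len // PACKET_S)
        total = int(lengths.sum())
        if total == 0:
            continue
        offsets = np.arange(total) - np.repeat(np.cumsum(lengths) - lengths, lengths)
        chunks.append(
            pd.DataFrame(
                {
                    "t": np.repeat(start_t, lengths) + PACKET_S * offsets,
                    "id_a": ids[np.repeat(ep_i, lengths)],
                    "id_b": ids[np.repeat(ep_j, lengths)],
                }
            )
        )
    if not chunks:
        records = pd.DataFrame(columns=["t", "id_a", "id_b"]).astype({"t": np.int64})
    else:
        records, _ = canonicalize_records(pd.concat(chunks, ignore_index=True))
    return drop_gap_records(records, config.gap_schedule, config.epoch)


def generate_dataset(config: SyntheticConfig, seed: int | None = None) -> SyntheticDataset:
    """Roster + contacts + ground truth, with sub-streams derived from one seed."""
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    roster_seed, contact_seed = [int(s.generate_state(1)[0]) for s in ss.spawn(2)]
    roster = generate_roster(config, roster_seed)
    modifiers = plant_outcome_effects(config, roster) if config.planted_effects else None
    records = generate_contacts(config, roster, contact_seed, rate_modifiers=modifiers)
    truth = {
        "config": config.to_dict(),
        "seed": base,
        "n_records": int(len(records)),
        "planted_effects": config.planted_effects,
    }
    return SyntheticDataset(roster=roster, records=records, truth=truth)


def expected_daily_episodes(config: SyntheticConfig, cat_a: str, cat_b: str, *, same_ward: bool, weekday: int = 0) -> float:
    """Closed-form expected episodes/day for one pair; used by calibration tests."""
    rate = config.pair_rate.get(pair_key(cat_a, cat_b), 0.0)
    lam = rate * float(np.sum(config.circadian_weights)) * config.dow_multipliers[weekday]
    if same_ward:
        lam *= config.same_ward_boost
    elif cat_a == "patient" and cat_b == "patient":
        lam *= config.cross_ward_patient_mult
    return lam
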