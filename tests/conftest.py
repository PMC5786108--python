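import datetime

import numpy as np
import pandas as pd
import pytest

from cpinet.synthetic_data import SyntheticConfig, generate_dataset, pair_key
from cpinet.types import GapSchedule

EPOCH = datetime.date(2009, 7, 6)  # Monday


@pytest.fixture(scope="session")
def small_config():
    """A small 2-ward hospital; quick to simulate, still multi-category."""
    return SyntheticConfig(
        n_days=14,
        epoch=EPOCH,
        ward_census={
            "W1": {"patient": 8, "HCW": 5, "physician": 1, "AHS": 2},
            "W2": {"patient": 8, "HCW": 5, "reeducation": 2},
            "W6_transversal": {"hospital_porter": 2, "logistic": 2},
        },
        gap_schedule=GapSchedule.from_pairs(
            [(EPOCH + datetime.timedelta(days=6), EPOCH + datetime.timedelta(days=7))]
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config, seed=7)


@pytest.fixture(scope="session")
def default_dataset():
    """One week of the default ~310-person hospital (no gaps)."""
    cfg = SyntheticConfig(n_days=7, epoch=EPOCH)
    return cfg, generate_dataset(cfg, seed=11)


def make_records(rows):
    """Records DataFrame from (t, id_a, id_b) tuples (already canonical or not)."""
    return pd.DataFrame(rows, columns=["t", "id_a", "id_b"]).astype({"t": np.int64})


@pytest.fixture
def tiny_records():
    return make_records


def brute_force_person_day_distinct(records, epoch):
    """Independent oracle: distinct partners per (id, date) straight from raw packets."""
    out = {}
    for t, a, b in records[["t", "id_a", "id_b"]].itertuples(index=False):
        date = epoch + datetime.timedelta(days=int(t) // 86400)
        out.setdefault((a, date), set()).add(b)
        out.setdefault((b, date), set()).add(a)
    return {k: len(v) for k, v in out.items()}


def brute_force_pair_day_duration(records, epoch):
    """Independent oracle: 30 s x packet count per (pair, date)."""
    out = {}
    for t, a, b in records[["t", "id_a", "id_b"]].itertuples(index=False):
        date = epoch + datetime.timedelta(days=int(t) // 86400)
        out[(a, b, date)] = out.get((a, b, date), 0) + 30
    return out


def brute_force_episodes(records, tolerance_s):
    """Independent O(n^2)-style oracle: per-pair run-length scan over sorted packets."""
    episodes = []
    for (a, b), grp in records.groupby(["id_a", "id_b"]):
        ts = sorted(grp["t"])
        run = [ts[0]]
        for t in ts[1:]:
            if t - run[-1] <= tolerance_s and t // 86400 == run[-1] // 86400:
                run.append(t)
            else:
                episodes.append((a, b, run[0], run[-1] + 30, len(run)))
                run = [t]
        episodes.append((a, b, run[0], run[-1] + 30, len(run)))
    return sorted(episodes)
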