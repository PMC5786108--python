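"""Ward-conditioned category x category mixing matrices.

Two kinds of matrix are produced per ward:

* ``distinct_frequency`` — cell (r, c) is the mean, over person-days of
  ward-attached category-r individuals, of the number of distinct category-c
  partners met that day (partners drawn from the whole hospital);
* ``cumulative_duration`` — cell (r, c) is the mean daily cumulative contact
  duration (minutes) over pair-days joining a ward-attached category-r member
  with a category-c member anywhere.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .contact_metrics import _directed_pair_days
from .types import Roster


@dataclasses.dataclass
class CategoryMatrix:
    ward: str
    kind: str  # "distinct_frequency" | "cumulative_duration"
    values: pd.DataFrame  # rows: ward categories, cols: hospital-wide categories
    support: pd.DataFrame  # per-cell count of averaged units

    def to_long(self) -> pd.DataFrame:
        rows = []
        for r in self.values.index:
            for c in self.values.columns:
                rows.append(
                    {
                        "ward": self.ward,
                        "kind": self.kind,
                        "row_cat": r,
                        "col_cat": c,
                        "value": self.values.loc[r, c],
                        "support": int(self.support.loc[r, c]),
                    }
                )
        return pd.DataFrame(rows)


def _roster_categories(roster: Roster) -> list[str]:
    return sorted({ind.category.value for ind in roster})


def _ward_categories(roster: Roster, ward: str) -> list[str]:
    return sorted({ind.category.value for ind in roster if ind.ward.value == ward})


def contact_matrix(
    pair_day_table: pd.DataFrame,
    person_day_table: pd.DataFrame,
    roster: Roster,
    ward: str,
) -> CategoryMatrix:
    """Mean daily distinct-partner counts for individuals attached to ``ward``.

    Denominators are all person-days of the (ward, row-category) group, so
    row sums equal the group's mean total daily distinct contacts.
    """
    all_cats = _roster_categories(roster)
    row_cats = _ward_categories(roster, ward)
    values = pd.DataFrame(np.nan, index=row_cats, columns=all_cats)
    support = pd.DataFrame(0, index=row_cats, columns=all_cats, dtype=int)
    if not row_cats:
        return CategoryMatrix(ward, "distinct_frequency", values, support)

    cat_map = roster.category_map()
    ward_map = roster.ward_map()
    pdays = person_day_table.copy()
    pdays["ward"] = pdays["id"].map(ward_map)
    pdays["category"] = pdays["id"].map(cat_map)
    group_n = (
        pdays.loc[pdays["ward"] == ward].groupby("category").size().reindex(row_cats, fill_value=0)
    )

    directed = _directed_pair_days(pair_day_table)
    directed["ward"] = directed["id"].map(ward_map)
    directed["category"] = directed["id"].map(cat_map)
    directed["partner_cat"] = directed["partner"].map(cat_map)
    sub = directed.loc[directed["ward"] == ward]
    partner_totals = (
        sub.groupby(["category", "partner_cat"]).size().unstack(fill_value=0)
        .reindex(index=row_cats, columns=all_cats, fill_value=0)
    )
    for r in row_cats:
        n = int(group_n[r])
        support.loc[r, :] = n
        if n > 0:
            values.loc[r, :] = partner_totals.loc[r, :] / n
    return CategoryMatrix(ward, "distinct_frequency", values, support)


def duration_matrix(
    pair_day_table: pd.DataFrame, roster: Roster, ward: str
) -> CategoryMatrix:
    """Mean pair-day contact duration (minutes/day) between ward categories
    (rows) and hospital-wide categories (columns); empty cells are missing
    with support 0."""
    all_cats = _roster_categories(roster)
    row_cats = _ward_categories(roster, ward)
    values = pd.DataFrame(np.nan, index=row_cats, columns=all_cats)
    support = pd.DataFrame(0, index=row_cats, columns=all_cats, dtype=int)
    if not row_cats or pair_day_table.empty:
        return CategoryMatrix(ward, "cumulative_duration", values, support)

    cat_map = roster.category_map()
    ward_map = roster.ward_map()
    directed = _directed_pair_days(pair_day_table)
    directed["row_ward"] = directed["id"].map(ward_map)
    directed["row_cat"] = directed["id"].map(cat_map)
    directed["col_cat"] = directed["partner"].map(cat_map)
    sub = directed.loc[directed["row_ward"] == ward].copy()
    # A pair-day must count once per cell; for row_cat == col_cat the two
    # orientations hit the same cell, so collapse them.
    lo = np.minimum(sub["id"], sub["partner"])
    hi = np.maximum(sub["id"], sub["partner"])
    sub["pair_id"] = lo + "|" + hi
    sub = sub.drop_duplicates(subset=["pair_id", "date", "row_cat", "col_cat"])
    grouped = sub.groupby(["row_cat", "col_cat"])["cum_duration_s"]
    means = (grouped.mean() / 60.0).unstack()
    counts = grouped.size().unstack(fill_value=0)
    values.update(means.reindex(index=row_cats, columns=all_cats))
    support.update(counts.reindex(index=row_cats, columns=all_cats, fill_value=0))
    return CategoryMatrix(ward, "cumulative_duration", values, support.astype(int))


def all_matrices(
    pair_day_table: pd.DataFrame,
    person_day_table: pd.DataFrame,
    roster: Roster,
) -> list[CategoryMatrix]:
    """Both matrix kinds for every ward with at least one attached individual."""
    wards = sorted({ind.ward.value for ind in roster})
    out = []
    for ward in wards:
        out.append(contact_matrix(pair_day_table, person_day_table, roster, ward))
        out.append(duration_matrix(pair_day_table, roster, ward))
    return out


def matrices_to_long(matrices: list[CategoryMatrix]) -> pd.DataFrame:
    return pd.concat([m.to_long() for m in matrices], ignore_index=True)


def plot_heatmap(matrix: CategoryMatrix, path: str) -> None:
    """Render a matrix as a heatmap PNG (reporting helper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    data = matrix.values.to_numpy(dtype=float)
    im = ax.imshow(data, cmap="viridis")
    ax.set_xticks(range(len(matrix.values.columns)), matrix.values.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.values.index)), matrix.values.index)
    label = "distinct partners/day" if matrix.kind == "distinct_frequency" else "minutes/day"
    fig.colorbar(im, ax=ax, label=label)
    ax.set_title(f"{matrix.ward} — {matrix.kind}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
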