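"""Individual-level event-history matrices.

An event-history chart shows one row per fly and one column per day of life,
coloured by the day's value of an event variable (corrected intake or eggs
laid).  The tested artifact here is the underlying matrix; rendering is a
thin optional layer on top.

Two kinds of undefined cell are kept distinct throughout: a day *after the
fly's death* (the row simply ends) and a day *within life with no
observation* (a missing reading).  On export the former serialises as an
empty cell and the latter as ``NA``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import CohortTable, Sex, intake_series


class EventVariable(str, enum.Enum):
    INTAKE = "intake"
    EGGS = "eggs"


@dataclass
class EventMatrix:
    """Fly-by-day values; rows ordered by death day descending, ties by fly_id."""

    fly_ids: list[str]
    death_days: list[int]
    values: np.ndarray  # shape (n_flies, max_day); NaN = within-life missing
    variable: EventVariable

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    def row(self, fly_id: str) -> np.ndarray:
        i = self.fly_ids.index(fly_id)
        return self.values[i, : self.death_days[i]]

    def column_means(self) -> np.ndarray:
        """Per-day mean over flies alive (and observed) that day."""
        out = np.full(self.n_days, np.nan)
        for d in range(self.n_days):
            vals = [
                self.values[i, d]
                for i in range(len(self.fly_ids))
                if d < self.death_days[i] and not np.isnan(self.values[i, d])
            ]
            if vals:
                out[d] = float(np.mean(vals))
        return out

    def row_sums(self) -> dict[str, float]:
        """Per-fly lifetime totals (missing days contribute nothing)."""
        return {
            fid: float(np.nansum(self.values[i, : self.death_days[i]]))
            for i, fid in enumerate(self.fly_ids)
        }


def build_event_matrix(table: CohortTable, variable: EventVariable) -> EventMatrix:
    """Assemble the cohort's event matrix for intake or egg production.

    The matrix has one column per day 1..max death day; cells within a fly's
    life that lack an observation are NaN, cells after death are undefined
    (masked by the row's death day).  Requesting eggs on a male cohort is an
    error.
    """
    if variable is EventVariable.EGGS and any(r.sex is not Sex.F for r in table.records):
        raise ValueError("egg event matrix requested on a cohort containing males")
    order = sorted(table.death_day, key=lambda fid: (-table.death_day[fid], fid))
    max_day = max(table.death_day.values())
    values = np.full((len(order), max_day), np.nan)
    index = {fid: i for i, fid in enumerate(order)}
    if variable is EventVariable.INTAKE:
        for fid in order:
            for day, val in intake_series(table, fid):
                values[index[fid], day - 1] = val
    else:
        for r in table.records:
            if r.eggs is not None and r.age_day <= table.death_day[r.fly_id]:
                values[index[r.fly_id], r.age_day - 1] = float(r.eggs)
    return EventMatrix(
        fly_ids=order,
        death_days=[table.death_day[f] for f in order],
        values=values,
        variable=variable,
    )


def export_event_matrix(m: EventMatrix, path: str | Path) -> None:
    """Write the matrix as a wide CSV (one row per fly, one column per day).

    After-death cells are empty; within-life missing cells are ``NA``.
    """
    cols = [f"d{d}" for d in range(1, m.n_days + 1)]
    rows = []
    for i, fid in enumerate(m.fly_ids):
        row: dict[str, object] = {"fly_id": fid, "death_day": m.death_days[i], "variable": m.variable.value}
        for d in range(m.n_days):
            if d >= m.death_days[i]:
                cell = ""
            elif np.isnan(m.values[i, d]):
                cell = "NA"
            else:
                cell = repr(float(m.values[i, d]))
            row[cols[d]] = cell
        rows.append(row)
    pd.DataFrame(rows, columns=["fly_id", "death_day", "variable"] + cols).to_csv(path, index=False)


def read_event_matrix(path: str | Path) -> EventMatrix:
    """Inverse of :func:`export_event_matrix`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    day_cols = [c for c in df.columns if c.startswith("d") and c[1:].isdigit()]
    n_days = len(day_cols)
    fly_ids = df["fly_id"].tolist()
    death_days = [int(v) for v in df["death_day"]]
    variable = EventVariable(df["variable"].iloc[0])
    values = np.full((len(fly_ids), n_days), np.nan)
    for i in range(len(fly_ids)):
        for d in range(n_days):
            cell = df.iloc[i][f"d{d + 1}"]
            if cell not in ("", "NA"):
                values[i, d] = float(cell)
    return EventMatrix(fly_ids=fly_ids, death_days=death_days, values=values, variable=variable)


def plot_event_matrix(m: EventMatrix, path: str | Path, cmap: str = "viridis") -> None:
    """Render the matrix as a raster chart (one row per fly, one column per day)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    masked = np.ma.masked_invalid(
        np.where(
            np.arange(m.n_days)[None, :] < np.array(m.death_days)[:, None], m.values, np.nan
        )
    )
    fig, ax = plt.subplots(figsize=(8, max(2, 0.12 * len(m.fly_ids))))
    im = ax.imshow(masked, aspect="auto", interpolation="nearest", cmap=cmap)
    ax.set_xlabel("age (days)")
    ax.set_ylabel("individual (longest-lived first)")
    fig.colorbar(im, ax=ax, label=m.variable.value)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
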