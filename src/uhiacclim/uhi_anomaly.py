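"""Urban heat island anomalies from gridded daily temperatures.

The UHI anomaly of a grid square is the long-run mean of its daily
temperature excess over the same-day city-wide mean:

    UHIa_g = (1/n_g) sum_j (T_gj - T_j),

with T_j the unweighted mean over the grids reporting on day j and n_g
the number of days grid g reports.  A single configurable temperature
statistic is used for both the grid and city terms (an excess of one
statistic over a different one would not be an anomaly).  Grids are
then ranked by anomaly and split into ten equal-count decile groups,
group 1 coolest through group 10 hottest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DecileGroups", "compute_uhia", "assign_deciles"]


def compute_uhia(grid_temps: pd.DataFrame) -> pd.DataFrame:
    """Per-grid UHI anomaly and contributing-day count.

    Parameters
    ----------
    grid_temps : long-format frame with columns ``grid_id``, ``date``,
        ``temp`` (degC), one record per (grid, day).

    Returns
    -------
    DataFrame with columns ``grid_id``, ``uhia``, ``n_days``.
    """
    req = {"grid_id", "date", "temp"}
    if not req.issubset(grid_temps.columns):
        raise ValueError(f"grid temperature table needs columns {sorted(req)}")
    if len(grid_temps) == 0:
        raise ValueError("empty grid temperature table")
    if grid_temps.duplicated(["grid_id", "date"]).any():
        dup = grid_temps[grid_temps.duplicated(["grid_id", "date"])].iloc[0]
        raise ValueError(f"duplicate record for grid {dup['grid_id']} on {dup['date']}")
    temp = pd.to_numeric(grid_temps["temp"], errors="coerce")
    if not np.isfinite(temp).all():
        raise ValueError("non-finite temperatures in grid table")

    df = grid_temps.assign(temp=temp)
    city_mean = df.groupby("date")["temp"].transform("mean")
    excess = df["temp"] - city_mean
    out = (
        df.assign(excess=excess)
        .groupby("grid_id", sort=True)["excess"]
        .agg(uhia="mean", n_days="size")
        .reset_index()
    )
    if (out["n_days"] == 0).any():
        g = out.loc[out["n_days"] == 0, "grid_id"].iloc[0]
        raise ValueError(f"grid {g} has no overlapping days with the city series")
    return out


@dataclass
class DecileGroups:
    """Grid-to-group assignment and per-group mean anomalies."""

    assignment: pd.DataFrame  # grid_id, uhia, n_days, group
    summary: pd.DataFrame  # group, mean_uhia, n_grids

    @property
    def group_of(self):
        return dict(zip(self.assignment["grid_id"], self.assignment["group"]))

    @property
    def mean_uhia(self):
        return dict(zip(self.summary["group"], self.summary["mean_uhia"]))


def assign_deciles(anomalies: pd.DataFrame, n_groups: int = 10) -> DecileGroups:
    """Classify grids into equal-count anomaly groups (1 = coolest).

    Rank-based split: grids sorted by (uhia, grid_id); when the count
    is not divisible by ``n_groups`` the lower groups take the extra
    grids; ties are broken by grid_id order so the assignment is
    deterministic and order-invariant.
    """
    if anomalies["grid_id"].duplicated().any():
        g = anomalies.loc[anomalies["grid_id"].duplicated(), "grid_id"].iloc[0]
        raise ValueError(f"duplicate grid_id {g!r}")
    n = len(anomalies)
    if n < n_groups:
        raise ValueError(f"need >= {n_groups} grids for a {n_groups}-group classification, got {n}")
    ranked = anomalies.sort_values(["uhia", "grid_id"], kind="stable").reset_index(drop=True)
    base, extra = divmod(n, n_groups)
    sizes = [base + (1 if k < extra else 0) for k in range(n_groups)]
    ranked["group"] = np.repeat(np.arange(1, n_groups + 1), sizes)
    summary = (
        ranked.groupby("group")["uhia"]
        .agg(mean_uhia="mean", n_grids="size")
        .reset_index()
    )
    return DecileGroups(ranked, summary)
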