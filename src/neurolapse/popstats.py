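"""Population time-series aggregation and fold changes.

Per-frame summaries of the whole culture: number of cells and per-cell
means of neurite length, node count and cell body size, plus fold-change
series against a baseline frame (day 0 by default).  Hypothesis testing is
deliberately left to external statistical software; ``export_tidy``
produces the long-format table those tools expect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import ImagingSchedule

__all__ = [
    "PopulationTimeSeries",
    "population_timeseries",
    "fold_change",
    "export_tidy",
    "plot_timeseries",
    "plot_node_category_stack",
]

METRICS = ["n_cells", "mean_neurite_um", "mean_node_count", "mean_area_um2"]


@dataclass
class PopulationTimeSeries:
    """Per-frame population summaries; ``frame`` indexed, with a day column."""

    data: pd.DataFrame  # columns: frame, day, n_cells, mean_* metrics

    def fold_change(self, metric: str, baseline_frame: int = 0) -> pd.Series:
        return fold_change(
            self.data.set_index("frame")[metric], baseline_frame, metric=metric
        )


def population_timeseries(
    observations: pd.DataFrame, schedule: ImagingSchedule
) -> PopulationTimeSeries:
    """Aggregate a tidy observation table frame by frame.

    Empty frames yield ``n_cells = 0`` with NaN means (flagged, not zero).
    """
    n_frames = schedule.n_frames
    rows = []
    for f in range(n_frames):
        sub = observations[observations["frame"] == f] if len(observations) else None
        if sub is None or len(sub) == 0:
            rows.append(
                {
                    "frame": f,
                    "day": schedule.frame_time_days(f),
                    "n_cells": 0,
                    "mean_neurite_um": np.nan,
                    "mean_node_count": np.nan,
                    "mean_area_um2": np.nan,
                }
            )
            continue
        rows.append(
            {
                "frame": f,
                "day": schedule.frame_time_days(f),
                "n_cells": int(len(sub)),
                "mean_neurite_um": float(sub["neurite_um"].mean()),
                "mean_node_count": float(sub["node_count"].mean()),
                "mean_area_um2": float(sub["area_um2"].mean()),
            }
        )
    return PopulationTimeSeries(pd.DataFrame(rows))


def fold_change(series, baseline_frame: int = 0, metric: str = "") -> pd.Series:
    """Elementwise division by the value at ``baseline_frame``.

    Raises on a zero (or missing) baseline, naming the metric and frame.
    """
    s = pd.Series(series, dtype=float)
    try:
        base = float(s.loc[baseline_frame])
    except KeyError:
        raise ValueError(
            f"baseline frame {baseline_frame} absent for metric {metric or 'series'}"
        )
    if base == 0 or np.isnan(base):
        raise ValueError(
            f"zero/undefined baseline for metric {metric or 'series'} at frame "
            f"{baseline_frame}"
        )
    return s / base


def export_tidy(
    results: dict[str, dict[int, PopulationTimeSeries]],
) -> pd.DataFrame:
    """Long-format table: one row per (condition, replicate, frame, metric).

    ``results`` maps condition name -> replicate id -> time series.  Columns:
    condition, replicate, frame, day, metric, value.
    """
    rows = []
    for condition, reps in results.items():
        for replicate, ts in reps.items():
            for rec in ts.data.itertuples():
                for metric in METRICS:
                    rows.append(
                        {
                            "condition": condition,
                            "replicate": replicate,
                            "frame": rec.frame,
                            "day": rec.day,
                            "metric": metric,
                            "value": getattr(rec, metric),
                        }
                    )
    return pd.DataFrame(
        rows, columns=["condition", "replicate", "frame", "day", "metric", "value"]
    )


def plot_timeseries(
    series_by_condition: dict[str, PopulationTimeSeries],
    metric: str,
    ax=None,
):
    """Line plot of one metric over days, one line per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, ts in series_by_condition.items():
        ax.plot(ts.data["day"], ts.data[metric], label=name)
    ax.set_xlabel("day")
    ax.set_ylabel(metric)
    ax.legend()
    return ax


def plot_node_category_stack(category_counts: pd.DataFrame, ax=None):
    """Stacked area plot of cells with 0/1/2/3/4+ nodes over time.

    ``category_counts`` columns: day, n0, n1, n2, n3, n4plus.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cols = ["n0", "n1", "n2", "n3", "n4plus"]
    ax.stackplot(
        category_counts["day"],
        *[category_counts[c] for c in cols],
        labels=["0", "1", "2", "3", "4+"],
    )
    ax.set_xlabel("day")
    ax.set_ylabel("# cells")
    ax.legend(title="nodes")
    return ax
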