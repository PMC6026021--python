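"""Single-cell fate metrics: class assignment, class A hours, fate-transition
tables, and reverse tracking of rescuable class B cells.

Cells are classified by their (smoothed) node count: **class A** has three
or more nodes (the most developed cells), **class B** one or two, **class C**
none.  Class C cells die quickly and cannot be tracked, so fate tables tally
only cells that are class A or B at the analysis-window start.  "Class A
hours" is the time a cell that starts the window in class A remains in
class A before first transitioning to B or C (or disappearing).  Reverse
tracking compares rescued versus unrescued class B cells — rescued means
reaching class A after trophic-factor addback — on their morphometrics at
the addback frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import numpy as np
import pandas as pd

from .synthetic_data import ImagingSchedule
from .tracking import Trajectory, compute_velocity

__all__ = [
    "ClassLabel",
    "AnalysisWindow",
    "FateTransitionTable",
    "ReverseTrackSummary",
    "smooth_node_series",
    "classify",
    "classify_trajectory",
    "class_a_hours",
    "fate_transition_table",
    "reverse_track",
    "node_category_counts",
    "reference_fate_tables",
    "fate_table_residuals",
]


class ClassLabel(str, Enum):
    A = "A"  # >= 3 nodes
    B = "B"  # 1-2 nodes
    C = "C"  # 0 nodes


@dataclass(frozen=True)
class AnalysisWindow:
    start_day: float
    end_day: float
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not (self.start_day < self.end_day and self.start_frame < self.end_frame):
            raise ValueError("window start must precede end")

    @classmethod
    def from_days(
        cls, start_day: float, end_day: float, schedule: ImagingSchedule
    ) -> "AnalysisWindow":
        sf = schedule.frame_of_day(start_day)
        ef = schedule.frame_of_day(end_day)
        if ef >= schedule.n_frames:
            raise ValueError("window end beyond the movie")
        return cls(start_day, end_day, sf, ef)

    @property
    def length_hours(self) -> float:
        return (self.end_day - self.start_day) * 24.0


@dataclass
class FateTransitionTable:
    """Counts of class transitions over an analysis window for one condition."""

    condition: str
    tracked_a: float
    tracked_b: float
    a_to_a: float
    a_to_b: float
    a_to_c: float
    b_to_a: float
    b_to_b: float
    b_to_c: float

    @property
    def total_tracked(self) -> float:
        return self.tracked_a + self.tracked_b

    def residuals(self) -> tuple[float, float]:
        """(class-A identity error, class-B identity error)."""
        return (
            abs(self.a_to_a + self.a_to_b + self.a_to_c - self.tracked_a),
            abs(self.b_to_a + self.b_to_b + self.b_to_c - self.tracked_b),
        )

    def validate(self, tol: float = 1e-9) -> None:
        ra, rb = self.residuals()
        if ra > tol or rb > tol:
            raise ValueError(
                f"fate table for {self.condition!r} violates conservation: "
                f"A residual {ra:g}, B residual {rb:g}"
            )


@dataclass
class ReverseTrackSummary:
    """Group means/SEMs at the addback frame for rescued or unrescued cells."""

    group: str  # rescued | unrescued
    n: int
    mean_node_count: float
    sem_node_count: float
    mean_cell_body_size: float
    sem_cell_body_size: float
    mean_compactness: float
    sem_compactness: float
    mean_velocity: float
    sem_velocity: float


def smooth_node_series(series, window: int = 3) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    s = pd.Series(np.asarray(series, dtype=float))
    if s.empty:
        return np.empty(0)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def classify(node_value: float) -> ClassLabel:
    """Class from a (possibly smoothed) node count; half-up rounding."""
    if node_value < 0:
        raise ValueError("node count cannot be negative")
    n = int(math.floor(node_value + 0.5))
    if n >= 3:
        return ClassLabel.A
    if n >= 1:
        return ClassLabel.B
    return ClassLabel.C


def classify_trajectory(
    traj: Trajectory, smooth_window: int = 3, use_smoothed: bool = True
) -> list[ClassLabel]:
    """Per-frame class labels along a trajectory."""
    series = traj.node_series()
    if use_smoothed:
        series = smooth_node_series(series, smooth_window)
    return [classify(v) for v in series]


def class_a_hours(
    traj: Trajectory,
    window: AnalysisWindow,
    schedule: ImagingSchedule,
    smooth_window: int = 3,
    use_smoothed: bool = True,
) -> float | None:
    """Hours a window-start class A cell remains class A.

    Returns None for cells that are absent or not class A at the window
    start.  The clock stops at the first non-A frame, at disappearance, or
    at the window end, whichever comes first.
    """
    if traj.observation_at(window.start_frame) is None:
        return None
    labels = classify_trajectory(traj, smooth_window, use_smoothed)
    start_i = window.start_frame - traj.start_frame
    if labels[start_i] is not ClassLabel.A:
        return None
    last = min(window.end_frame, traj.end_frame)
    for f in range(window.start_frame + 1, last + 1):
        if labels[f - traj.start_frame] is not ClassLabel.A:
            return (f - window.start_frame) * schedule.interval_hours
    return (last - window.start_frame) * schedule.interval_hours


def fate_transition_table(
    trajectories: list[Trajectory],
    window: AnalysisWindow,
    schedule: ImagingSchedule,
    condition: str = "",
    smooth_window: int = 3,
    use_smoothed: bool = True,
) -> FateTransitionTable:
    """Tally (start class -> end class) over the window.

    Start class comes from the window-start frame; only class A and B cells
    are tracked (class C cells die too fast to follow).  A trajectory that
    terminates before the window end is assigned end class C.
    """
    counts = {(a, b): 0 for a in "AB" for b in "ABC"}
    for traj in trajectories:
        if traj.observation_at(window.start_frame) is None:
            continue
        labels = classify_trajectory(traj, smooth_window, use_smoothed)
        start = labels[window.start_frame - traj.start_frame]
        if start is ClassLabel.C:
            continue
        if traj.end_frame < window.end_frame:
            end = ClassLabel.C
        else:
            end = labels[window.end_frame - traj.start_frame]
        counts[(start.value, end.value)] += 1
    tab = FateTransitionTable(
        condition=condition,
        tracked_a=sum(counts[("A", e)] for e in "ABC"),
        tracked_b=sum(counts[("B", e)] for e in "ABC"),
        a_to_a=counts[("A", "A")],
        a_to_b=counts[("A", "B")],
        a_to_c=counts[("A", "C")],
        b_to_a=counts[("B", "A")],
        b_to_b=counts[("B", "B")],
        b_to_c=counts[("B", "C")],
    )
    tab.validate()
    return tab


def _mean_sem(values: list[float]) -> tuple[float, float]:
    if not values:
        return (float("nan"), float("nan"))
    arr = np.asarray(values, dtype=float)
    sem = arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else 0.0
    return float(arr.mean()), float(sem)


def reverse_track(
    trajectories: list[Trajectory],
    addback_frame: int,
    window: AnalysisWindow,
    schedule: ImagingSchedule,
    smooth_window: int = 3,
    use_smoothed: bool = True,
) -> tuple[ReverseTrackSummary, ReverseTrackSummary]:
    """Compare rescued vs unrescued class B cells at the addback frame.

    Rescued = class B at the addback frame and reaching class A at any frame
    in (addback, window end].  Morphometrics (node count, cell body size,
    compactness, velocity) are read back at the addback frame itself.
    """
    groups: dict[str, dict[str, list[float]]] = {
        g: {"nodes": [], "size": [], "compact": [], "vel": []}
        for g in ("rescued", "unrescued")
    }
    for traj in trajectories:
        obs = traj.observation_at(addback_frame)
        if obs is None:
            continue
        labels = classify_trajectory(traj, smooth_window, use_smoothed)
        if labels[addback_frame - traj.start_frame] is not ClassLabel.B:
            continue
        last = min(window.end_frame, traj.end_frame)
        rescued = any(
            labels[f - traj.start_frame] is ClassLabel.A
            for f in range(addback_frame + 1, last + 1)
        )
        g = groups["rescued" if rescued else "unrescued"]
        g["nodes"].append(float(obs.node_count))
        g["size"].append(obs.area_um2)
        g["compact"].append(obs.compactness)
        vel = compute_velocity(traj, schedule)
        i = addback_frame - traj.start_frame
        g["vel"].append(float(vel[i - 1]) if 1 <= i <= len(vel) else float("nan"))

    out = []
    for name in ("rescued", "unrescued"):
        g = groups[name]
        mn, sn = _mean_sem(g["nodes"])
        ms, ss = _mean_sem(g["size"])
        mc, sc = _mean_sem(g["compact"])
        mv, sv = _mean_sem([v for v in g["vel"] if not math.isnan(v)])
        out.append(
            ReverseTrackSummary(
                group=name,
                n=len(g["nodes"]),
                mean_node_count=mn,
                sem_node_count=sn,
                mean_cell_body_size=ms,
                sem_cell_body_size=ss,
                mean_compactness=mc,
                sem_compactness=sc,
                mean_velocity=mv,
                sem_velocity=sv,
            )
        )
    return out[0], out[1]


def node_category_counts(node_counts) -> np.ndarray:
    """Counts of cells with 0, 1, 2, 3 and >= 4 nodes (stacked-plot bins)."""
    arr = np.asarray(node_counts, dtype=int)
    if arr.size and arr.min() < 0:
        raise ValueError("node counts cannot be negative")
    out = np.zeros(5, dtype=int)
    for k in range(4):
        out[k] = int((arr == k).sum())
    out[4] = int((arr >= 4).sum())
    return out


# ---------------------------------------------------------------------------
# published reference fate tables


def reference_fate_tables() -> pd.DataFrame:
    """Published mean per-condition fate-transition counts (n=5 replicates).

    Two studies are bundled: trophic-factor addback (window day 6-14) and a
    soma-protective small molecule (day 0-14).  These printed means serve as
    an arithmetic consistency fixture for the conservation identities; a few
    rows of the addback table carry transcription artifacts and fail them
    (see ``fate_table_residuals``).
    """
    with resources.files("neurolapse.data").joinpath(
        "reference_fate_tables.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def fate_table_residuals(df: pd.DataFrame) -> pd.DataFrame:
    """Conservation residuals per row of a reference-format fate table.

    Adds columns: ``resid_a`` (|A outcomes - tracked A|), ``resid_b``,
    ``resid_total`` (|tracked A + tracked B - total|), and ``consistent``
    (all three within 0.05, the printed rounding).
    """
    out = df.copy()
    out["resid_a"] = (
        out["a_to_a"] + out["a_to_b"] + out["a_to_c"] - out["tracked_a"]
    ).abs()
    out["resid_b"] = (
        out["b_to_a"] + out["b_to_b"] + out["b_to_c"] - out["tracked_b"]
    ).abs()
    out["resid_total"] = (
        out["tracked_a"] + out["tracked_b"] - out["total_tracked"]
    ).abs()
    tol = 0.05
    out["consistent"] = (
        (out["resid_a"] <= tol) & (out["resid_b"] <= tol) & (out["resid_total"] <= tol)
    )
    return out
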