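"""Frame-to-frame identity assignment and trajectory assembly.

Cells are linked between consecutive frames by scoring candidate pairs on
position, morphology and overlap, then solving the optimal one-to-one
assignment over admissible pairs.  The contract mirrors the tracking
settings of the original assay software: minimum object size 50 px, maximum
search range 200 px, split threshold 0.90 (splits are ignored: the larger
fragment keeps the id), merge threshold 0.70 (fused objects are partitioned
between the two identities by nearest-seed pixel assignment), minimum
trajectory length 5 frames.

The link score is a convex combination

    total = 0.5 * max(0, 1 - d / search_range)
          + 0.25 * min(A1, A2) / max(A1, A2)
          + 0.25 * IoU(masks)

which is zero whenever the centroid displacement exceeds the search range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .morphometry import CellObservation
from .synthetic_data import ImagingSchedule, SimGroundTruth

__all__ = [
    "TrackingParams",
    "LinkScore",
    "Trajectory",
    "score_link",
    "link_frames",
    "build_trajectories",
    "compute_velocity",
    "trajectories_from_observations",
    "trajectories_from_ground_truth",
]


@dataclass(frozen=True)
class TrackingParams:
    min_object_size: int = 50
    max_object_size: int = 999999
    max_search_range: float = 200.0
    split_threshold: float = 0.90  # retained for config fidelity; splits ignored
    merge_threshold: float = 0.70
    min_trajectory_length: int = 5
    w_distance: float = 0.5
    w_area: float = 0.25
    w_overlap: float = 0.25
    gap_closing: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.split_threshold <= 1 and 0 <= self.merge_threshold <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.max_search_range <= 0:
            raise ValueError("max_search_range must be positive")


@dataclass(frozen=True)
class LinkScore:
    distance_term: float
    area_similarity_term: float
    overlap_term: float
    total: float


@dataclass
class Trajectory:
    """A tracked cell identity: ordered observations over contiguous frames."""

    cell_id: int
    observations: list[CellObservation] = field(default_factory=list)
    end_reason: str = "movie_end"  # movie_end | lost | merged

    @property
    def start_frame(self) -> int:
        return self.observations[0].frame

    @property
    def end_frame(self) -> int:
        return self.observations[-1].frame

    def __len__(self) -> int:
        return len(self.observations)

    def observation_at(self, frame: int) -> CellObservation | None:
        i = frame - self.start_frame
        if 0 <= i < len(self.observations):
            return self.observations[i]
        return None

    def node_series(self) -> np.ndarray:
        return np.array([o.node_count for o in self.observations], dtype=float)


def _mask_iou(a: CellObservation, b: CellObservation) -> float:
    pa, pb = a.mask_pixels(), b.mask_pixels()
    if pa is None or pb is None:
        return _disk_iou(a, b)
    sa = {tuple(p) for p in pa}
    sb = {tuple(p) for p in pb}
    inter = len(sa & sb)
    union = len(sa | sb)
    return inter / union if union else 0.0


def _disk_iou(a: CellObservation, b: CellObservation) -> float:
    """IoU of equal-area disks at the observed centroids (mask fallback)."""
    r1 = math.sqrt(a.area_px / math.pi)
    r2 = math.sqrt(b.area_px / math.pi)
    d = math.dist(a.centroid_px, b.centroid_px)
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        inter = math.pi * min(r1, r2) ** 2
    else:
        q1 = math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
        q2 = math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
        inter = (
            q1 * r1 * r1
            + q2 * r2 * r2
            - 0.5 * (r1 * r1 * math.sin(2 * q1) + r2 * r2 * math.sin(2 * q2))
        )
    union = math.pi * (r1 * r1 + r2 * r2) - inter
    return inter / union if union > 0 else 0.0


def score_link(
    obs_t: CellObservation,
    obs_t1: CellObservation,
    params: TrackingParams,
    search_range: float | None = None,
) -> LinkScore:
    """Score a candidate identity link between consecutive frames."""
    rng = search_range if search_range is not None else params.max_search_range
    d = math.dist(obs_t.centroid_px, obs_t1.centroid_px)
    if d > rng:
        return LinkScore(0.0, 0.0, 0.0, 0.0)
    dist_term = max(0.0, 1.0 - d / rng)
    a1, a2 = obs_t.area_px, obs_t1.area_px
    area_term = min(a1, a2) / max(a1, a2) if max(a1, a2) > 0 else 0.0
    overlap_term = _mask_iou(obs_t, obs_t1)
    total = (
        params.w_distance * dist_term
        + params.w_area * area_term
        + params.w_overlap * overlap_term
    )
    return LinkScore(dist_term, area_term, overlap_term, total)


def link_frames(
    frame_t: list[CellObservation],
    frame_t1: list[CellObservation],
    params: TrackingParams,
    search_range: float | None = None,
) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """Optimal one-to-one assignment between two observation lists.

    Returns ``(pairs, unmatched_t, unmatched_t1)`` where pairs are
    ``(i, j, score)`` index tuples into the input lists.  Only pairs with a
    positive score are admissible; the assignment maximizes the summed score
    (ties resolved deterministically by the solver's row order, i.e. lower
    previous-frame index first).
    """
    if not frame_t or not frame_t1:
        return [], list(range(len(frame_t))), list(range(len(frame_t1)))
    scores = np.zeros((len(frame_t), len(frame_t1)))
    for i, a in enumerate(frame_t):
        for j, b in enumerate(frame_t1):
            scores[i, j] = score_link(a, b, params, search_range).total
    cost = -scores
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(i), int(j), float(scores[i, j]))
        for i, j in zip(rows, cols)
        if scores[i, j] > 0.0
    ]
    matched_t = {i for i, _, _ in pairs}
    matched_t1 = {j for _, j, _ in pairs}
    unmatched_t = [i for i in range(len(frame_t)) if i not in matched_t]
    unmatched_t1 = [j for j in range(len(frame_t1)) if j not in matched_t1]
    return pairs, unmatched_t, unmatched_t1


def _partition_observation(
    obs: CellObservation,
    seeds: list[tuple[float, float]],
) -> list[CellObservation]:
    """Split a fused observation between identities by nearest-seed pixels.

    Seeds are (x, y) centroids of the identities entering the merge.  Node
    markers follow their nearest seed; neurite length splits by area share.
    """
    pix = obs.mask_pixels()
    if pix is None:
        # no mask: fall back to synthetic equal split at the seed midpoints
        n = len(seeds)
        return [
            replace(
                obs,
                centroid_px=s,
                area_px=obs.area_px / n,
                area_um2=obs.area_um2 / n,
                neurite_length_um=obs.neurite_length_um / n,
                node_positions_px=[],
                mask=None,
                mask_bbox=None,
            )
            for s in seeds
        ]
    seed_rc = np.array([(y, x) for x, y in seeds])
    d2 = ((pix[:, None, :] - seed_rc[None, :, :]) ** 2).sum(axis=2)
    owner = np.argmin(d2, axis=1)
    out: list[CellObservation] = []
    area_scale = obs.area_um2 / obs.area_px if obs.area_px else 0.0
    for k in range(len(seeds)):
        mine = pix[owner == k]
        if len(mine) == 0:
            mine = pix[[int(np.argmin(d2[:, k]))]]
        rmin, cmin = mine.min(axis=0)
        rmax, cmax = mine.max(axis=0) + 1
        m = np.zeros((rmax - rmin, cmax - cmin), dtype=bool)
        m[mine[:, 0] - rmin, mine[:, 1] - cmin] = True
        cy, cx = mine.mean(axis=0)
        nodes = [
            (x, y)
            for x, y in obs.node_positions_px
            if np.argmin(((seed_rc - (y, x)) ** 2).sum(axis=1)) == k
        ]
        frac = len(mine) / obs.area_px
        out.append(
            replace(
                obs,
                centroid_px=(float(cx), float(cy)),
                area_px=float(len(mine)),
                area_um2=float(len(mine)) * area_scale,
                node_count=len(nodes),
                node_positions_px=nodes,
                neurite_length_um=obs.neurite_length_um * frac,
                mask_bbox=(int(rmin), int(cmin), int(rmax), int(cmax)),
                mask=m,
            )
        )
    return out


def build_trajectories(
    frames: list[list[CellObservation]],
    params: TrackingParams,
) -> list[Trajectory]:
    """Assemble trajectories by iterative linking over the whole movie.

    Fused objects whose score against each incoming identity exceeds
    ``merge_threshold`` are partitioned between those identities; splits are
    ignored (the best-scoring fragment keeps the id, others found new
    candidates); identities lost for one frame may be re-acquired at twice
    the search range (gap closing), with the skipped frame filled by linear
    interpolation.  Trajectories shorter than ``min_trajectory_length``
    frames are discarded.
    """
    if not frames:
        return []

    active: list[Trajectory] = []
    pending: list[Trajectory] = []  # lost at the previous step, gap-closable
    finished: list[Trajectory] = []
    next_id = 1
    for obs in sorted(frames[0], key=lambda o: o.label):
        if params.min_object_size <= obs.area_px <= params.max_object_size:
            active.append(Trajectory(cell_id=next_id, observations=[obs]))
            next_id += 1

    for f in range(1, len(frames)):
        new_obs = [
            o
            for o in sorted(frames[f], key=lambda o: o.label)
            if params.min_object_size <= o.area_px <= params.max_object_size
        ]
        tails = [t.observations[-1] for t in active]
        pairs, un_prev, un_next = link_frames(tails, new_obs, params)
        assignment: dict[int, int] = {i: j for i, j, _ in pairs}

        # --- merge handling: an unmatched identity whose mask fused with a
        # matched object is partitioned back out of it
        consumed_merges: list[tuple[int, int]] = []  # (loser idx, winner idx)
        taken = dict(assignment)
        for i in list(un_prev):
            best_j, best_s = -1, 0.0
            for j, o in enumerate(new_obs):
                s = score_link(tails[i], o, params).total
                if s > best_s:
                    best_j, best_s = j, s
            if best_j < 0:
                continue
            owner = next((i2 for i2, j2 in taken.items() if j2 == best_j), None)
            if owner is None:
                continue
            s_owner = score_link(tails[owner], new_obs[best_j], params).total
            if best_s > params.merge_threshold and s_owner > params.merge_threshold:
                consumed_merges.append((i, owner))
                un_prev.remove(i)

        merged_pieces: dict[int, CellObservation] = {}
        for loser, owner in consumed_merges:
            j = assignment[owner]
            seeds = [tails[owner].centroid_px, tails[loser].centroid_px]
            piece_owner, piece_loser = _partition_observation(new_obs[j], seeds)
            merged_pieces[owner] = piece_owner
            merged_pieces[loser] = piece_loser

        still_active: list[Trajectory] = []
        lost_now: list[Trajectory] = []
        for i, t in enumerate(active):
            if i in merged_pieces:
                t.observations.append(merged_pieces[i])
                still_active.append(t)
            elif i in assignment:
                t.observations.append(new_obs[assignment[i]])
                still_active.append(t)
            else:
                lost_now.append(t)

        # --- gap closing: identities lost at f-1 try to re-acquire at f
        matched_next = set(assignment.values())
        leftover = [j for j in un_next if j not in matched_next]
        revived: set[int] = set()
        if params.gap_closing and pending and leftover:
            p_tails = [t.observations[-1] for t in pending]
            cand = [new_obs[j] for j in leftover]
            gpairs, _, _ = link_frames(
                p_tails, cand, params, search_range=2.0 * params.max_search_range
            )
            for i, j, _s in gpairs:
                t = pending[i]
                prev = t.observations[-1]
                nxt = cand[j]
                mid = replace(
                    prev,
                    frame=f - 1,
                    centroid_px=(
                        0.5 * (prev.centroid_px[0] + nxt.centroid_px[0]),
                        0.5 * (prev.centroid_px[1] + nxt.centroid_px[1]),
                    ),
                    mask=None,
                    mask_bbox=None,
                )
                t.observations.extend([mid, nxt])
                still_active.append(t)
                revived.add(i)
                leftover[j] = -1  # consumed
            leftover = [j for j in leftover if j >= 0]

        for i, t in enumerate(pending):
            if i not in revived:
                t.end_reason = "lost"
                finished.append(t)
        pending = lost_now

        for j in leftover:
            still_active.append(Trajectory(cell_id=next_id, observations=[new_obs[j]]))
            next_id += 1
        active = still_active

    for t in pending:
        t.end_reason = "lost"
        finished.append(t)
    for t in active:
        t.end_reason = "movie_end"
        finished.append(t)

    kept = [t for t in finished if len(t) >= params.min_trajectory_length]
    kept.sort(key=lambda t: t.cell_id)
    return kept


def compute_velocity(
    traj: Trajectory,
    schedule: ImagingSchedule,
) -> np.ndarray:
    """Per-interval speed in um/h from consecutive centroid displacements."""
    if len(traj) < 2:
        return np.empty(0)
    pts = np.array([o.centroid_px for o in traj.observations])
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1) * schedule.pixel_size_um
    return steps / schedule.interval_hours


def trajectories_from_ground_truth(gt: SimGroundTruth) -> list[Trajectory]:
    """Perfect trajectories read directly off simulator truth.

    One trajectory per cell, spanning frame 0 until death (dead cells are
    invisible, so the trajectory simply ends).  Bypasses rendering,
    segmentation and linking — the oracle input for the fate pipeline.
    """
    px = gt.schedule.pixel_size_um
    trajs: list[Trajectory] = []
    for cell_id in sorted(s.cell_id for s in gt.frames[0]):
        obs: list[CellObservation] = []
        for f, s in enumerate(gt.cell_series(cell_id)):
            if not s.alive:
                break
            obs.append(
                CellObservation(
                    frame=f,
                    label=cell_id,
                    centroid_px=(s.position_um[0] / px, s.position_um[1] / px),
                    area_px=math.pi * (s.soma_radius_um / px) ** 2,
                    area_um2=math.pi * s.soma_radius_um**2,
                    compactness=1.0,
                    mean_intensity=1.0,
                    node_count=s.node_count,
                    neurite_length_um=s.total_neurite_um,
                )
            )
        if obs:
            trajs.append(
                Trajectory(
                    cell_id=cell_id,
                    observations=obs,
                    end_reason=(
                        "movie_end" if len(obs) == gt.n_frames else "lost"
                    ),
                )
            )
    return trajs


def trajectories_from_observations(
    df: pd.DataFrame,
    params: TrackingParams | None = None,
    pixel_size_um: float = 1.25,
) -> list[Trajectory]:
    """Track a tidy observation table (schema of ``observations_to_dataframe``).

    Areas in the table are in um^2; they are converted to px^2 for the size
    gates and scoring.
    """
    params = params or TrackingParams()
    frames: list[list[CellObservation]] = []
    if len(df) == 0:
        return []
    n_frames = int(df["frame"].max()) + 1
    for f in range(n_frames):
        sub = df[df["frame"] == f]
        obs = [
            CellObservation(
                frame=f,
                label=int(r.label),
                centroid_px=(float(r.x), float(r.y)),
                area_px=float(r.area_um2) / pixel_size_um**2,
                area_um2=float(r.area_um2),
                compactness=float(r.compactness),
                mean_intensity=float(r.intensity),
                node_count=int(r.node_count),
                neurite_length_um=float(r.neurite_um),
            )
            for r in sub.itertuples()
        ]
        frames.append(obs)
    return build_trajectories(frames, params)
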