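"""Agent-based simulator of motor-neuron morphodynamics with a fluorescence renderer.

The simulator emulates a single imaging field of Islet1::GFP-like motor
neurons on a dark background: bright compact somata with curvilinear
neurites, imaged at a fixed cadence (default every 6 h for 14 days).  Each
cell carries a true state — position, soma radius, node count (number of
neurite attachment points on the soma), per-neurite lengths, alive flag —
that evolves by discrete per-frame stochastic updates:

* under trophic-factor (TF) support, nodes are gained (Bernoulli per step),
  neurites elongate and the soma grows;
* without support, nodes are lost, neurites retract, the soma shrinks and a
  death hazard applies that increases as nodes fall below the class-A
  threshold of three;
* TF addback restores supported dynamics for cells flagged rescuable at the
  addback frame (the probability of rescue increases with node count and
  soma radius at that time);
* a soma-protective agent lowers the death hazard to its supported value and
  slows node loss, but never enables node gain — somata persist while
  neurites fail to regrow.

The renderer turns true states into 16-bit grayscale frames, which makes
every downstream stage (segmentation, tracking, fate analysis) testable
against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

__all__ = [
    "ImagingSchedule",
    "ConditionSpec",
    "DynamicsRates",
    "RenderNoise",
    "NeuronState",
    "SimulationConfig",
    "SimGroundTruth",
    "simulate_culture",
    "render_frame",
    "simulate_timelapse",
    "ground_truth_observations",
    "default_conditions",
]

#: node count at and above which a cell is "well developed" (class A); the
#: death hazard grows per node missing below this.
CLASS_A_NODES = 3

#: hard cap on nodes per cell so attachment points stay angularly resolvable.
MAX_NODES = 8

#: minimum angular separation between neurite attachment points (radians).
MIN_NODE_ANGLE_SEP = math.radians(40.0)


@dataclass(frozen=True)
class ImagingSchedule:
    """Imaging cadence and field geometry.

    Frame 0 is day 0; frame ``f`` maps to time ``f * interval_hours``.
    """

    interval_hours: float = 6.0
    duration_days: float = 14.0
    field_size_um: tuple[float, float] = (3080.0, 3080.0)
    pixel_size_um: float = 1.25

    def __post_init__(self) -> None:
        if self.interval_hours <= 0 or self.duration_days <= 0:
            raise ValueError("interval_hours and duration_days must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration_days * 24.0 / self.interval_hours)) + 1

    def frame_time_hours(self, frame: int) -> float:
        return frame * self.interval_hours

    def frame_time_days(self, frame: int) -> float:
        return frame * self.interval_hours / 24.0

    def frame_of_day(self, day: float) -> int:
        """Frame index closest to a nominal day (exact for on-grid days)."""
        return int(round(day * 24.0 / self.interval_hours))

    @property
    def field_size_px(self) -> tuple[int, int]:
        w, h = self.field_size_um
        return (int(round(h / self.pixel_size_um)), int(round(w / self.pixel_size_um)))


@dataclass(frozen=True)
class ConditionSpec:
    """A culture condition: when TF support is withdrawn/restored, drug effect.

    ``tf_withdraw_day=None`` means continuous support (TF+).  ``drug_effect``
    is either ``"none"`` or ``"soma_protective"`` (a kenpaullone-like agent
    that preserves somata without restoring neurites).
    """

    name: str
    tf_withdraw_day: float | None = None
    tf_addback_day: float | None = None
    drug_effect: str = "none"
    drug_start_day: float | None = None

    def __post_init__(self) -> None:
        if self.drug_effect not in ("none", "soma_protective"):
            raise ValueError(f"unknown drug_effect {self.drug_effect!r}")
        if self.tf_addback_day is not None:
            if self.tf_withdraw_day is None:
                raise ValueError("tf_addback_day requires tf_withdraw_day")
            if self.tf_addback_day <= self.tf_withdraw_day:
                raise ValueError("tf_addback_day must be after tf_withdraw_day")
        if self.drug_start_day is not None and self.drug_effect == "none":
            raise ValueError("drug_start_day requires drug_effect != 'none'")

    def tf_supported(self, day: float) -> bool:
        """Whether the medium contains trophic factors at ``day`` (ignoring
        per-cell rescuability, which gates the addback response)."""
        if self.tf_withdraw_day is None:
            return True
        if day < self.tf_withdraw_day:
            return True
        return self.tf_addback_day is not None and day >= self.tf_addback_day

    def drug_active(self, day: float) -> bool:
        if self.drug_effect == "none":
            return False
        start = self.drug_start_day if self.drug_start_day is not None else 0.0
        return day >= start


@dataclass(frozen=True)
class DynamicsRates:
    """Per-day rates of the discrete-time morphodynamic process.

    Node gain/loss are Bernoulli events per frame interval with probability
    ``rate * dt`` (dt in days, clipped to [0, 1]).  The death hazard is
    ``base + hazard_per_missing_node * max(0, 3 - node_count)`` per day,
    likewise converted to a clipped per-step probability.  Under the
    soma-protective drug the hazard reverts to ``base`` and node loss is
    multiplied by ``drug_node_loss_factor``.
    """

    node_gain_rate_per_day: float = 0.30
    node_loss_rate_per_day: float = 0.15
    neurite_growth_um_per_day: float = 8.0
    neurite_retract_um_per_day: float = 12.0
    soma_growth_um_per_day: float = 0.4
    soma_shrink_um_per_day: float = 0.5
    base_death_hazard_per_day: float = 0.01
    hazard_per_missing_node: float = 0.15
    motility_um_per_step: float = 6.0
    drug_node_loss_factor: float = 0.25
    soma_radius_jitter_um: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "node_gain_rate_per_day",
            "node_loss_rate_per_day",
            "neurite_retract_um_per_day",
            "soma_shrink_um_per_day",
            "base_death_hazard_per_day",
            "hazard_per_missing_node",
            "motility_um_per_step",
            "drug_node_loss_factor",
            "soma_radius_jitter_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def death_hazard_per_day(self, node_count: int) -> float:
        missing = max(0, CLASS_A_NODES - node_count)
        return self.base_death_hazard_per_day + self.hazard_per_missing_node * missing


@dataclass(frozen=True)
class RenderNoise:
    """Intensity model of the rendered frames (16-bit counts)."""

    background_level: float = 100.0
    gaussian_sd: float = 8.0
    soma_intensity: float = 1000.0
    neurite_intensity: float = 400.0

    def __post_init__(self) -> None:
        if not (self.soma_intensity > self.neurite_intensity > self.background_level):
            raise ValueError(
                "require soma_intensity > neurite_intensity > background_level"
            )
        if self.gaussian_sd < 0 or self.background_level < 0:
            raise ValueError("noise levels must be nonnegative")


@dataclass
class NeuronState:
    """True state of one cell at one frame."""

    cell_id: int
    position_um: tuple[float, float]  # (x, y)
    soma_radius_um: float
    node_count: int
    neurite_lengths_um: list[float] = field(default_factory=list)
    neurite_angles_rad: list[float] = field(default_factory=list)
    alive: bool = True
    rescuable: bool = False

    def __post_init__(self) -> None:
        if len(self.neurite_lengths_um) != self.node_count:
            raise ValueError("neurite_lengths_um must have node_count entries")
        if len(self.neurite_angles_rad) != self.node_count:
            raise ValueError("neurite_angles_rad must have node_count entries")

    @property
    def total_neurite_um(self) -> float:
        return float(sum(self.neurite_lengths_um))


@dataclass(frozen=True)
class SimulationConfig:
    n_cells: int = 110
    schedule: ImagingSchedule = field(default_factory=ImagingSchedule)
    condition: ConditionSpec = field(default_factory=lambda: ConditionSpec("TF+"))
    rates: DynamicsRates = field(default_factory=DynamicsRates)
    noise: RenderNoise = field(default_factory=RenderNoise)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.schedule.n_frames < 2:
            raise ValueError("schedule must produce at least 2 frames")


@dataclass
class SimGroundTruth:
    """Per-frame true states for every cell (dead cells retain their id)."""

    frames: list[list[NeuronState]]
    condition: ConditionSpec
    schedule: ImagingSchedule

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_cells(self) -> int:
        return len(self.frames[0])

    def cell_series(self, cell_id: int) -> list[NeuronState]:
        idx = {s.cell_id: i for i, s in enumerate(self.frames[0])}[cell_id]
        return [fr[idx] for fr in self.frames]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f, states in enumerate(self.frames):
            for s in states:
                rows.append(
                    {
                        "frame": f,
                        "cell_id": s.cell_id,
                        "x_um": s.position_um[0],
                        "y_um": s.position_um[1],
                        "soma_radius_um": s.soma_radius_um,
                        "node_count": s.node_count,
                        "total_neurite_um": s.total_neurite_um,
                        "alive": s.alive,
                        "rescuable": s.rescuable,
                    }
                )
        return pd.DataFrame(rows)


def default_conditions(addback_day: float = 6.0) -> list[ConditionSpec]:
    """The four canonical condition regimes of the assay."""
    return [
        ConditionSpec("TF+"),
        ConditionSpec("TF-", tf_withdraw_day=1.0),
        ConditionSpec(
            f"addback_day{addback_day:g}",
            tf_withdraw_day=1.0,
            tf_addback_day=addback_day,
        ),
        ConditionSpec(
            "soma_protective",
            tf_withdraw_day=1.0,
            drug_effect="soma_protective",
            drug_start_day=1.0,
        ),
    ]


# ---------------------------------------------------------------------------
# initial placement and per-cell initialisation


def _placement_margin_um(schedule: ImagingSchedule) -> float:
    short_side = min(schedule.field_size_um)
    return min(150.0, short_side / 6.0)


def _sample_positions(
    n: int, schedule: ImagingSchedule, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Low-clumping placement: rejection sampling with a minimum separation."""
    w, h = schedule.field_size_um
    margin = _placement_margin_um(schedule)
    min_sep = 50.0
    positions: list[tuple[float, float]] = []
    attempts = 0
    while len(positions) < n:
        attempts += 1
        if attempts > 20000 * n:
            raise RuntimeError(
                f"could not place {n} cells with {min_sep} um separation in "
                f"a {w:g} x {h:g} um field"
            )
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        ok = all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in positions)
        if ok:
            positions.append((x, y))
    return positions


def _new_neurite_angle(
    existing: list[float], rng: np.random.Generator
) -> float | None:
    """Pick an attachment angle at least MIN_NODE_ANGLE_SEP from existing ones."""
    for _ in range(40):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        if all(
            min(abs(theta - a), 2.0 * math.pi - abs(theta - a)) >= MIN_NODE_ANGLE_SEP
            for a in existing
        ):
            return theta
    return None


def _initial_state(cell_id: int, pos, rng: np.random.Generator) -> NeuronState:
    node_count = min(MAX_NODES, 1 + int(rng.poisson(1.8)))
    angles: list[float] = []
    lengths: list[float] = []
    for _ in range(node_count):
        theta = _new_neurite_angle(angles, rng)
        if theta is None:
            break
        angles.append(theta)
        lengths.append(max(20.0, rng.normal(60.0, 15.0)))
    node_count = len(angles)
    radius = float(np.clip(rng.normal(9.0, 1.2), 5.0, 14.0))
    return NeuronState(
        cell_id=cell_id,
        position_um=(float(pos[0]), float(pos[1])),
        soma_radius_um=radius,
        node_count=node_count,
        neurite_lengths_um=lengths,
        neurite_angles_rad=angles,
    )


# ---------------------------------------------------------------------------
# dynamics


def _rescue_probability(node_count: int, soma_radius_um: float) -> float:
    """Logistic rescue probability, increasing in nodes and soma size.

    One extra node is worth about 1.5 um of soma radius in the rescue odds,
    so both covariates carry real signal for reverse tracking.
    """
    z = 1.2 * (node_count - 1.5) + 0.8 * (soma_radius_um - 7.0)
    return 1.0 / (1.0 + math.exp(-z))


def simulate_culture(config: SimulationConfig) -> SimGroundTruth:
    """Run the agent-based dynamics; no rendering.

    Deterministic given ``config.seed``.  Dead cells freeze their state
    (``alive=False`` from the death frame onward) and keep their ``cell_id``.
    """
    schedule, cond, rates = config.schedule, config.condition, config.rates
    rng = np.random.default_rng(config.seed)
    dt = schedule.interval_hours / 24.0
    w_um, h_um = schedule.field_size_um
    margin = _placement_margin_um(schedule)

    positions = _sample_positions(config.n_cells, schedule, rng)
    current = [_initial_state(i + 1, p, rng) for i, p in enumerate(positions)]
    frames: list[list[NeuronState]] = [
        [
            replace(
                s,
                neurite_lengths_um=list(s.neurite_lengths_um),
                neurite_angles_rad=list(s.neurite_angles_rad),
            )
            for s in current
        ]
    ]

    addback_frame = (
        schedule.frame_of_day(cond.tf_addback_day)
        if cond.tf_addback_day is not None
        else None
    )

    for f in range(1, schedule.n_frames):
        day_start = schedule.frame_time_days(f - 1)

        for s in current:
            if not s.alive:
                continue

            supported = cond.tf_supported(day_start)
            if (
                cond.tf_addback_day is not None
                and day_start >= cond.tf_addback_day
                and not s.rescuable
            ):
                supported = False
            drug = cond.drug_active(day_start) and not supported

            # death draw from start-of-step state
            hazard = rates.death_hazard_per_day(s.node_count)
            if supported or drug:
                hazard = rates.base_death_hazard_per_day
            p_death = min(1.0, hazard * dt)
            if rng.random() < p_death:
                s.alive = False
                continue

            if supported:
                p_gain = min(1.0, rates.node_gain_rate_per_day * dt)
                if rng.random() < p_gain and s.node_count < MAX_NODES:
                    theta = _new_neurite_angle(s.neurite_angles_rad, rng)
                    if theta is not None:
                        s.neurite_angles_rad.append(theta)
                        s.neurite_lengths_um.append(20.0)
                        s.node_count += 1
                s.neurite_lengths_um = [
                    l + rates.neurite_growth_um_per_day * dt
                    for l in s.neurite_lengths_um
                ]
                s.soma_radius_um = min(
                    16.0,
                    s.soma_radius_um
                    + rates.soma_growth_um_per_day * dt
                    + rng.normal(0.0, rates.soma_radius_jitter_um),
                )
            else:
                loss_rate = rates.node_loss_rate_per_day
                if drug:
                    loss_rate *= rates.drug_node_loss_factor
                p_loss = min(1.0, loss_rate * dt)
                if s.node_count > 0 and rng.random() < p_loss:
                    shortest = int(np.argmin(s.neurite_lengths_um))
                    s.neurite_lengths_um.pop(shortest)
                    s.neurite_angles_rad.pop(shortest)
                    s.node_count -= 1
                s.neurite_lengths_um = [
                    max(8.0, l - rates.neurite_retract_um_per_day * dt)
                    for l in s.neurite_lengths_um
                ]
                shrink = rates.soma_shrink_um_per_day * dt
                if drug:
                    shrink = 0.0
                s.soma_radius_um = max(
                    4.0, s.soma_radius_um - shrink + rng.normal(0.0, rates.soma_radius_jitter_um)
                )

            # isotropic random walk with fixed step length, reflected into
            # the margin box so rendered cells stay inside the field
            if rates.motility_um_per_step > 0:
                theta = rng.uniform(0.0, 2.0 * math.pi)
                x = s.position_um[0] + rates.motility_um_per_step * math.cos(theta)
                y = s.position_um[1] + rates.motility_um_per_step * math.sin(theta)
                x = _reflect(x, margin, w_um - margin)
                y = _reflect(y, margin, h_um - margin)
                s.position_um = (x, y)

        # rescue flags are drawn from the state at the addback frame itself,
        # just before restored TFs can act, and recorded with that frame
        if addback_frame is not None and f == addback_frame:
            for s in current:
                if s.alive:
                    p = _rescue_probability(s.node_count, s.soma_radius_um)
                    s.rescuable = bool(rng.random() < p)

        frames.append(
            [
                replace(
                    s,
                    neurite_lengths_um=list(s.neurite_lengths_um),
                    neurite_angles_rad=list(s.neurite_angles_rad),
                )
                for s in current
            ]
        )

    return SimGroundTruth(frames=frames, condition=cond, schedule=schedule)


def _reflect(v: float, lo: float, hi: float) -> float:
    if lo >= hi:  # degenerate tiny field
        return min(max(v, lo), lo)
    while v < lo or v > hi:
        if v < lo:
            v = 2 * lo - v
        if v > hi:
            v = 2 * hi - v
    return v


# ---------------------------------------------------------------------------
# rendering


def _neurite_path_px(
    state: NeuronState,
    node_idx: int,
    pixel_size_um: float,
    obstacles: np.ndarray | None = None,
) -> np.ndarray:
    """Pixel polyline of one neurite, stable across frames for a given cell.

    The stroke leaves the soma boundary radially at the recorded attachment
    angle and meanders with a small deterministic curvature seeded from
    (cell_id, node index), so a growing neurite keeps its shape over time.
    ``obstacles`` is an (n, 3) array of (x_px, y_px, r_px) soma disks the
    stroke steers around — growth cones deflect at cell bodies rather than
    running over them, while neurite-neurite crossings are left alone.
    """
    wiggle_rng = np.random.default_rng([state.cell_id, node_idx, 7919])
    theta = state.neurite_angles_rad[node_idx]
    length_px = state.neurite_lengths_um[node_idx] / pixel_size_um
    r_px = state.soma_radius_um / pixel_size_um
    cx = state.position_um[0] / pixel_size_um
    cy = state.position_um[1] / pixel_size_um

    step = 2.0
    n_steps = max(1, int(math.ceil(length_px / step)))
    pts = np.empty((n_steps + 1, 2))
    x = cx + r_px * math.cos(theta)
    y = cy + r_px * math.sin(theta)
    pts[0] = (y, x)
    heading = theta
    remaining = length_px
    for i in range(1, n_steps + 1):
        # mean-reverting heading keeps the stroke a smooth outward arc
        # instead of a curling random walk
        heading += wiggle_rng.normal(0.0, 0.08) + 0.2 * _wrap_angle(theta - heading)
        if obstacles is not None and len(obstacles):
            dx = x - obstacles[:, 0]
            dy = y - obstacles[:, 1]
            dist = np.hypot(dx, dy)
            clearance = dist - obstacles[:, 2]
            k = int(np.argmin(clearance))
            if clearance[k] < 5.0:
                away = math.atan2(dy[k], dx[k])
                heading += 0.8 * _wrap_angle(away - heading)
        d = min(step, remaining)
        remaining -= d
        x += d * math.cos(heading)
        y += d * math.sin(heading)
        pts[i] = (y, x)
    return pts


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def render_frame(
    states: list[NeuronState],
    schedule: ImagingSchedule,
    noise: RenderNoise,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Render live cells into a 16-bit grayscale frame.

    Somata are filled disks at ``soma_intensity``; each neurite is a smooth
    curvilinear stroke (3 px wide at the default pixel size) at
    ``neurite_intensity`` starting on the soma boundary.  Additive Gaussian
    noise rides on a flat background.  Dead cells are not drawn.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    shape = schedule.field_size_px
    canvas = np.zeros(shape, dtype=np.float64)
    # plus-shaped 3 px brush, equivalent to dilating a 1 px line by disk(1)
    brush = np.array([(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)])

    px = schedule.pixel_size_um
    live = [s for s in states if s.alive]
    all_disks = np.array(
        [
            (s.position_um[0] / px, s.position_um[1] / px, s.soma_radius_um / px)
            for s in live
        ]
    )

    for idx, s in enumerate(live):
        # other cells' somata are steering obstacles for this cell's neurites
        obstacles = np.delete(all_disks, idx, axis=0) if len(live) > 1 else None
        # neurites first; the soma disk overdraws the attachment ends
        for k in range(s.node_count):
            pts = _neurite_path_px(s, k, schedule.pixel_size_um, obstacles)
            ipts = np.round(pts).astype(int)
            segs = []
            for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
                rr, cc = draw_line(r0, c0, r1, c1)
                segs.append(np.column_stack([rr, cc]))
            path = np.concatenate(segs)
            thick = (path[:, None, :] + brush[None, :, :]).reshape(-1, 2)
            ok = (
                (thick[:, 0] >= 0)
                & (thick[:, 0] < shape[0])
                & (thick[:, 1] >= 0)
                & (thick[:, 1] < shape[1])
            )
            thick = thick[ok]
            np.maximum.at(
                canvas, (thick[:, 0], thick[:, 1]), noise.neurite_intensity
            )
        r_px = s.soma_radius_um / schedule.pixel_size_um
        rr, cc = draw_disk(
            (s.position_um[1] / schedule.pixel_size_um,
             s.position_um[0] / schedule.pixel_size_um),
            r_px,
            shape=shape,
        )
        canvas[rr, cc] = noise.soma_intensity

    canvas += noise.background_level
    if noise.gaussian_sd > 0:
        canvas += rng.normal(0.0, noise.gaussian_sd, size=shape)
    return np.clip(np.round(canvas), 0, 65535).astype(np.uint16)


def simulate_timelapse(
    config: SimulationConfig,
) -> tuple[np.ndarray, SimGroundTruth]:
    """Simulate dynamics and render every frame.

    Returns a ``(n_frames, H, W)`` uint16 stack and the ground truth; the two
    share frame indexing.  Byte-identical on re-run for a fixed config.
    """
    gt = simulate_culture(config)
    noise_rng = np.random.default_rng([config.seed, 104729])
    stack = np.stack(
        [
            render_frame(states, config.schedule, config.noise, seed=noise_rng)
            for states in gt.frames
        ]
    )
    return stack, gt


# ---------------------------------------------------------------------------
# ground-truth views for downstream stages


def ground_truth_observations(gt: SimGroundTruth) -> pd.DataFrame:
    """Per-frame observation table taken directly from true states.

    Only live cells appear (mirroring what segmentation could ever see);
    columns match the measured-observation schema where meaningful.
    """
    px = gt.schedule.pixel_size_um
    rows = []
    for f, states in enumerate(gt.frames):
        for s in states:
            if not s.alive:
                continue
            area_um2 = math.pi * s.soma_radius_um**2
            rows.append(
                {
                    "frame": f,
                    "label": s.cell_id,
                    "x": s.position_um[0] / px,
                    "y": s.position_um[1] / px,
                    "area_um2": area_um2,
                    "compactness": 1.0,
                    "intensity": 1.0,
                    "node_count": s.node_count,
                    "neurite_um": s.total_neurite_um,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "frame",
            "label",
            "x",
            "y",
            "area_um2",
            "compactness",
            "intensity",
            "node_count",
            "neurite_um",
        ],
    )
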