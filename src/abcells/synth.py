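"""Synthetic ground truth: motion models, rendered scenes, metric panels.

Everything downstream is benchmarked against this generator: single
trajectories with known motion laws (Brownian, persistent, directed,
arrested), multi-cell scenes with divisions and detection dropouts
rendered as noisy ellipse polygons, and grouped AR(1) metric panels for
calibrating the statistics engine. All outputs are deterministic per
seed (NumPy PCG64 generator throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .geometry import Polygon
from .ingest import Detection, FrameDetections
from .motility import Trajectory
from .stats import SeriesPanel

__all__ = [
    "Brownian",
    "Persistent",
    "Directed",
    "Arrested",
    "SceneTruth",
    "gen_trajectory",
    "gen_scene",
    "gen_grouped_series",
]

RNG_ALGORITHM = "PCG64"  # pinned for cross-platform reproducibility


@dataclass(frozen=True)
class Brownian:
    """Isotropic random walk: r_{t+1} = r_t + N(0, σ²I). Units px/frame."""

    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class Persistent:
    """Constant-speed walk whose heading diffuses; φ∈[0,1] is persistence.

    Heading noise is wrapped-normal with scale (1−φ)·π, so φ=1 walks
    straight and φ=0 reorients almost freely.
    """

    speed: float
    phi: float

    def __post_init__(self):
        if self.speed < 0 or not 0.0 <= self.phi <= 1.0:
            raise ValueError("need speed >= 0 and phi in [0, 1]")


@dataclass(frozen=True)
class Directed:
    """Deterministic drift r_{t+1} = r_t + v."""

    vx: float
    vy: float


@dataclass(frozen=True)
class Arrested:
    """Two-state Markov switch between a moving state and full stop.

    ``p_stop`` is P(move→stop) per frame, ``p_go`` is P(stop→move); the
    moving state steps like Brownian(sigma). Emulates episodic bursts
    of movement on an arrested baseline.
    """

    p_stop: float
    p_go: float
    sigma: float = 2.0

    def __post_init__(self):
        for p in (self.p_stop, self.p_go):
            if not 0.0 <= p <= 1.0:
                raise ValueError("transition probabilities must be in [0, 1]")


MotionModel = Union[Brownian, Persistent, Directed, Arrested]


def gen_trajectory(
    model: MotionModel,
    T: int,
    seed: Optional[int] = None,
    start: Sequence[float] = (0.0, 0.0),
    track_id: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Simulate one trajectory of T positions under the given motion law."""
    if T < 2:
        raise ValueError("need T >= 2 frames")
    if rng is None:
        rng = np.random.default_rng(seed)
    pos = np.empty((T, 2))
    pos[0] = np.asarray(start, dtype=float)

    if isinstance(model, Brownian):
        steps = rng.normal(0.0, model.sigma, size=(T - 1, 2))
    elif isinstance(model, Directed):
        steps = np.tile([model.vx, model.vy], (T - 1, 1))
    elif isinstance(model, Persistent):
        heading = rng.uniform(0, 2 * np.pi)
        steps = np.empty((T - 1, 2))
        scale = (1.0 - model.phi) * np.pi
        for t in range(T - 1):
            heading += rng.normal(0.0, scale)
            steps[t] = model.speed * np.array([np.cos(heading), np.sin(heading)])
    elif isinstance(model, Arrested):
        moving = True  # start in the moving state
        steps = np.zeros((T - 1, 2))
        for t in range(T - 1):
            if moving and rng.random() < model.p_stop:
                moving = False
            elif not moving and rng.random() < model.p_go:
                moving = True
            if moving:
                steps[t] = rng.normal(0.0, model.sigma, size=2)
    else:
        raise ValueError(f"unknown motion model {model!r}")

    pos[1:] = pos[0] + np.cumsum(steps, axis=0)
    return Trajectory(track_id=track_id, frames=np.arange(T), positions=pos)


# ----------------------------------------------------------------------
# rendered multi-cell scenes


@dataclass
class SceneTruth:
    """Ground truth emitted alongside a rendered scene."""

    polygons: dict[int, dict[int, Polygon]] = field(default_factory=dict)
    # frame -> id -> polygon (only objects present/visible in truth)
    centroids: dict[int, dict[int, np.ndarray]] = field(default_factory=dict)
    lineage: list[tuple[int, int, tuple[int, int]]] = field(default_factory=list)
    # (frame, parent_id, (child_a, child_b)); parent id continues as child_a
    dropouts: list[tuple[int, int]] = field(default_factory=list)
    # (frame, id) withheld from the emitted detections

    def frames(self) -> list[int]:
        return sorted(self.polygons)

    def objects_at(self, frame: int) -> dict[int, Polygon]:
        return self.polygons.get(frame, {})

    def track_ids(self) -> list[int]:
        ids: set[int] = set()
        for objs in self.polygons.values():
            ids.update(objs)
        return sorted(ids)

    def division_events(self) -> list[tuple[int, int, tuple[int, int]]]:
        return list(self.lineage)


def _cell_shape(rng: np.random.Generator, base_radius: float) -> tuple:
    """Random cell template: semi-axes, orientation, boundary noise."""
    ratio = rng.uniform(1.2, 3.0)
    b = base_radius / np.sqrt(ratio)
    a = b * ratio
    theta = rng.uniform(0, np.pi)
    noise = rng.normal(0.0, 0.06, size=16)
    return a, b, theta, noise


def _render_polygon(center: np.ndarray, shape: tuple) -> Polygon:
    a, b, theta, noise = shape
    t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    r_noise = 1.0 + noise
    x = a * np.cos(t) * r_noise
    y = b * np.sin(t) * r_noise
    ct, st = np.cos(theta), np.sin(theta)
    xy = np.c_[x * ct - y * st, x * st + y * ct] + center
    return Polygon(xy)


def gen_scene(
    n_cells: int,
    model: MotionModel,
    T: int,
    division_prob_per_frame: float = 0.0,
    dropout_prob: float = 0.0,
    image_size: tuple[int, int] = (1024, 1024),
    seed: Optional[int] = None,
    cell_radius: float = 18.0,
    min_spacing: Optional[float] = None,
    forced_divisions: Sequence[tuple[int, int]] = (),
) -> tuple[list[FrameDetections], SceneTruth]:
    """Render a multi-cell movie as per-frame polygon detections + truth.

    Cells start on a jittered grid (no initial overlap), move per the
    motion model, and are drawn as 16-vertex noisy ellipses. With
    ``division_prob_per_frame`` a cell may split into two daughters at
    60% parent area offset ±0.6 major axes along the parent's major
    axis; ``forced_divisions`` is a list of (cell_id, frame) divisions
    that happen deterministically. With ``dropout_prob`` a cell's
    detection is withheld for 1–3 frames (recorded in the truth).
    Reflecting boundaries keep cells inside the image.
    """
    rng = np.random.default_rng(seed)
    W, H = image_size
    if min_spacing is None:
        min_spacing = 4 * cell_radius
    cols = max(int((W - 2 * cell_radius) // min_spacing), 1)
    rows_n = max(int((H - 2 * cell_radius) // min_spacing), 1)
    if cols * rows_n < n_cells:
        raise ValueError(
            f"image {image_size} too small for {n_cells} cells at spacing {min_spacing}"
        )

    # jittered grid seeding
    slots = [(c, r) for r in range(rows_n) for c in range(cols)]
    chosen = rng.choice(len(slots), size=n_cells, replace=False)
    cells: dict[int, dict] = {}
    next_id = 1
    for s in chosen:
        c, r = slots[s]
        center = np.array(
            [
                cell_radius + (c + 0.5) * min_spacing,
                cell_radius + (r + 0.5) * min_spacing,
            ]
        ) + rng.uniform(-0.1, 0.1, 2) * min_spacing
        cells[next_id] = {
            "pos": center,
            "shape": _cell_shape(rng, cell_radius),
            "heading": rng.uniform(0, 2 * np.pi),
            "moving": True,
            "hidden_until": -1,
        }
        next_id += 1

    forced = {(int(cid), int(fr)) for cid, fr in forced_divisions}
    truth = SceneTruth()
    frames_out: list[FrameDetections] = []

    def _step(cell: dict) -> np.ndarray:
        if isinstance(model, Brownian):
            return rng.normal(0.0, model.sigma, 2)
        if isinstance(model, Directed):
            return np.array([model.vx, model.vy])
        if isinstance(model, Persistent):
            cell["heading"] += rng.normal(0.0, (1 - model.phi) * np.pi)
            return model.speed * np.array(
                [np.cos(cell["heading"]), np.sin(cell["heading"])]
            )
        if isinstance(model, Arrested):
            if cell["moving"] and rng.random() < model.p_stop:
                cell["moving"] = False
            elif not cell["moving"] and rng.random() < model.p_go:
                cell["moving"] = True
            return rng.normal(0.0, model.sigma, 2) if cell["moving"] else np.zeros(2)
        raise ValueError(f"unknown motion model {model!r}")

    for frame in range(T):
        if frame > 0:
            for cell in cells.values():
                p = cell["pos"] + _step(cell)
                p[0] = np.clip(p[0], cell_radius, W - cell_radius)
                p[1] = np.clip(p[1], cell_radius, H - cell_radius)
                cell["pos"] = p

        # divisions
        for cid in sorted(cells):
            cell = cells[cid]
            do_split = (cid, frame) in forced or (
                frame > 0
                and division_prob_per_frame > 0
                and rng.random() < division_prob_per_frame
            )
            if not do_split:
                continue
            a, b, theta, _ = cell["shape"]
            axis = np.array([np.cos(theta), np.sin(theta)])
            offset = 0.6 * a * axis
            s = np.sqrt(0.6)  # daughters at 60% of the parent area
            for sign, assign_parent in ((-1.0, True), (+1.0, False)):
                center = cell["pos"] + sign * offset
                center = np.clip(center, cell_radius, [W - cell_radius, H - cell_radius])
                # daughters keep the parent's orientation and aspect so the
                # split is geometrically recoverable; boundary noise is fresh
                state = {
                    "pos": center,
                    "shape": (a * s, b * s, theta, rng.normal(0.0, 0.06, 16)),
                    "heading": rng.uniform(0, 2 * np.pi),
                    "moving": True,
                    "hidden_until": -1,
                }
                if assign_parent:
                    cells[cid] = state  # parent id continues in daughter A
                else:
                    cells[next_id] = state
                    child_b = next_id
                    next_id += 1
            truth.lineage.append((frame, cid, (cid, child_b)))

        # dropouts
        for cid, cell in cells.items():
            if (
                dropout_prob > 0
                and cell["hidden_until"] < frame
                and rng.random() < dropout_prob
            ):
                cell["hidden_until"] = frame + int(rng.integers(1, 4)) - 1

        dets = []
        truth.polygons[frame] = {}
        truth.centroids[frame] = {}
        for cid in sorted(cells):
            cell = cells[cid]
            poly = _render_polygon(cell["pos"], cell["shape"])
            truth.polygons[frame][cid] = poly
            truth.centroids[frame][cid] = poly.centroid()
            if frame <= cell["hidden_until"]:
                truth.dropouts.append((frame, cid))
                continue
            dets.append(
                Detection(frame=frame, poly=poly, confidence=1.0, source="synthetic")
            )
        frames_out.append(FrameDetections(frame=frame, detections=dets))

    return frames_out, truth


# ----------------------------------------------------------------------
# grouped AR(1) metric panels


def gen_grouped_series(
    k: int,
    T: int,
    group_offsets: Optional[Sequence[float]] = None,
    ar1_phi: float = 0.0,
    noise_sd: float = 1.0,
    changepoint: Optional[int] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SeriesPanel:
    """k treatment series of length T around group means with AR(1) noise.

    X_g(t) = μ_g(t) + φ·(X_g(t−1) − μ_g(t−1)) + ε_t with ε ~ N(0, sd²).
    ``group_offsets`` are the μ_g; when a ``changepoint`` frame is given,
    each group's offset switches on only from that frame (mean 0 before),
    producing a divergence point for change-detection tests.
    """
    if k < 2:
        raise ValueError("need k >= 2 series")
    if T < 30:
        raise ValueError("need T >= 30 frames")
    if abs(ar1_phi) >= 1:
        raise ValueError("|phi| must be < 1 for stationarity")
    if group_offsets is None:
        group_offsets = [0.0] * k
    if len(group_offsets) != k:
        raise ValueError("group_offsets must have length k")
    if rng is None:
        rng = np.random.default_rng(seed)

    mu = np.zeros((k, T))
    for g, off in enumerate(group_offsets):
        if changepoint is None:
            mu[g, :] = off
        else:
            mu[g, changepoint:] = off

    eps = rng.normal(0.0, noise_sd, size=(k, T))
    x = np.empty((k, T))
    x[:, 0] = mu[:, 0] + eps[:, 0]
    for t in range(1, T):
        x[:, t] = mu[:, t] + ar1_phi * (x[:, t - 1] - mu[:, t - 1]) + eps[:, t]
    return SeriesPanel(x)
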