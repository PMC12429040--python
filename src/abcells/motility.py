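"""Trajectory linking and the static + dynamic motility descriptor suite.

Positions are in micrometers; the canonical kinematic unit is µm/frame
with the acquisition interval (seconds per frame) kept as metadata, so
the same numbers can be rescaled to physical time when needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "KinematicsSeries",
    "MotilityMetrics",
    "link_trajectories",
    "kinematics",
    "motility_metrics",
    "msd_lag",
    "sharp_turn_fraction",
    "aggregate",
    "DEFAULT_FRAME_INTERVAL_S",
    "DEFAULT_ARREST_THRESHOLD",
    "DEFAULT_MAX_STEP_UM",
    "DEFAULT_MAX_GAP_FRAMES",
]

DEFAULT_FRAME_INTERVAL_S = 350.0  # acquisition interval of the reference data
DEFAULT_ARREST_THRESHOLD = 0.2  # µm/frame — speed below this counts as arrest
DEFAULT_MAX_STEP_UM = 10.0  # nearest-neighbor linking bound per time step
DEFAULT_MAX_GAP_FRAMES = 2  # longest dropout bridged by interpolation
DEFAULT_SHARP_TURN_DEG = 90.0  # heading change counted as a sharp turn


@dataclass
class Trajectory:
    """Calibrated centroid time series of one cell."""

    track_id: int
    frames: np.ndarray  # strictly increasing 0-based indices
    positions: np.ndarray  # (n, 2) µm
    areas: Optional[np.ndarray] = None  # µm² per frame
    interpolated: Optional[np.ndarray] = None  # bool per frame

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if len(self.frames) != len(self.positions):
            raise ValueError("frames and positions length mismatch")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.frames), dtype=bool)
        if self.areas is not None:
            self.areas = np.asarray(self.areas, dtype=float)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class KinematicsSeries:
    displacement_um: np.ndarray  # n-1
    speed_um_per_frame: np.ndarray  # n-1
    acceleration_um_per_frame2: np.ndarray  # n-2
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    @property
    def speed_um_per_s(self) -> np.ndarray:
        return self.speed_um_per_frame / self.frame_interval_s


@dataclass(frozen=True)
class MotilityMetrics:
    """The twelve-descriptor dynamic summary of one trajectory.

    Angle-based entries are NaN when the trajectory never moves (the
    turning direction is undefined, which is distinct from zero).
    """

    msd: float
    directional_persistence: float
    meandering_index: float
    mean_turning_angle_deg: float
    radius_of_gyration: float
    arrest_coefficient: float
    shape_motion_coupling: float
    relative_motion_change: float
    velocity_cross_correlation: float
    directionality_ratio: float
    mean_speed: float
    mean_acceleration: float

    def as_dict(self) -> dict:
        return dict(vars(self))


FIG_METRIC_ORDER = [
    "msd",
    "directional_persistence",
    "meandering_index",
    "mean_turning_angle_deg",
    "radius_of_gyration",
    "arrest_coefficient",
    "shape_motion_coupling",
    "relative_motion_change",
    "velocity_cross_correlation",
    "directionality_ratio",
    "mean_speed",
    "mean_acceleration",
]


# ----------------------------------------------------------------------
# baseline linker


def link_trajectories(
    centroids_per_frame: Sequence[np.ndarray],
    max_step_um: float = DEFAULT_MAX_STEP_UM,
    max_gap: int = DEFAULT_MAX_GAP_FRAMES,
    areas_per_frame: Optional[Sequence[np.ndarray]] = None,
) -> list[Trajectory]:
    """Greedy mutual-nearest-neighbor linking of per-frame centroids.

    A link between consecutive frames must be shorter than
    ``max_step_um``; a cell silent for up to ``max_gap`` frames may
    re-link if its reappearance lies within the gap-scaled bound, and
    the missing positions are filled in by linear interpolation and
    flagged. Anything else starts a new track.
    """
    if max_step_um < 0:
        raise ValueError("max_step_um must be non-negative")

    # open track: id, frames list, positions list, areas list
    open_tracks: list[dict] = []
    done: list[dict] = []
    next_id = 0

    for f, pts in enumerate(centroids_per_frame):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        areas = (
            np.asarray(areas_per_frame[f], dtype=float)
            if areas_per_frame is not None
            else None
        )
        # candidate pairs (distance, track index, det index)
        cands = []
        for ti, tr in enumerate(open_tracks):
            dt = f - tr["frames"][-1]
            if dt - 1 > max_gap:
                continue
            allowed = dt * max_step_um
            d = np.linalg.norm(pts - tr["positions"][-1], axis=1)
            for di in np.where(d <= allowed)[0]:
                cands.append((d[di], ti, int(di)))
        cands.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in cands:
            if ti in used_t or di in used_d:
                continue
            tr = open_tracks[ti]
            dt = f - tr["frames"][-1]
            p0, p1 = tr["positions"][-1], pts[di]
            for g in range(1, dt):  # bridge the gap linearly
                w = g / dt
                tr["frames"].append(tr["frames"][-1] + 1)
                tr["positions"].append(p0 * (1 - w) + p1 * w)
                tr["interp"].append(True)
                tr["areas"].append(np.nan)
            tr["frames"].append(f)
            tr["positions"].append(p1)
            tr["interp"].append(False)
            tr["areas"].append(float(areas[di]) if areas is not None else np.nan)
            used_t.add(ti)
            used_d.add(di)
        # retire tracks that can no longer be extended
        still_open = []
        for ti, tr in enumerate(open_tracks):
            if f - tr["frames"][-1] - 1 >= max_gap and ti not in used_t:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        # births
        for di in range(len(pts)):
            if di in used_d:
                continue
            open_tracks.append(
                {
                    "id": next_id,
                    "frames": [f],
                    "positions": [pts[di]],
                    "interp": [False],
                    "areas": [float(areas[di]) if areas is not None else np.nan],
                }
            )
            next_id += 1

    done.extend(open_tracks)
    done.sort(key=lambda tr: tr["id"])
    out = []
    for tr in done:
        out.append(
            Trajectory(
                track_id=tr["id"],
                frames=np.array(tr["frames"]),
                positions=np.array(tr["positions"]),
                areas=np.array(tr["areas"]),
                interpolated=np.array(tr["interp"], dtype=bool),
            )
        )
    return out


# ----------------------------------------------------------------------
# kinematics and the twelve-metric summary


def kinematics(
    traj: Trajectory, frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
) -> KinematicsSeries:
    """Per-step displacement, speed and acceleration of one trajectory."""
    if len(traj) < 2:
        raise ValueError("kinematics needs at least 2 points")
    steps = np.diff(traj.positions, axis=0)
    disp = np.hypot(steps[:, 0], steps[:, 1])
    speed = disp.copy()  # µm per frame
    accel = np.diff(speed)
    return KinematicsSeries(disp, speed, accel, frame_interval_s)


def _turning_angles(traj: Trajectory) -> np.ndarray:
    """Angles (radians) between successive nonzero displacement vectors."""
    steps = np.diff(traj.positions, axis=0)
    lens = np.hypot(steps[:, 0], steps[:, 1])
    steps = steps[lens > 0]  # zero-length steps carry no direction
    if len(steps) < 2:
        return np.array([])
    a, b = steps[:-1], steps[1:]
    dot = (a * b).sum(axis=1)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return np.arctan2(np.abs(cross), dot)  # unsigned, in [0, π]


def motility_metrics(
    traj: Trajectory,
    arrest_threshold: float = DEFAULT_ARREST_THRESHOLD,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> MotilityMetrics:
    """Compute the twelve-descriptor summary for one trajectory.

    msd is the from-origin average of squared distances; persistence is
    the mean cosine of turning angles; meandering index and
    directionality ratio are both net displacement over path length
    (reported under both names); arrest coefficient is the fraction of
    steps with speed strictly below ``arrest_threshold``.
    """
    if len(traj) < 2:
        raise ValueError("motility metrics need at least 2 points")
    kin = kinematics(traj, frame_interval_s)
    r = traj.positions
    sq_from_origin = ((r[1:] - r[0]) ** 2).sum(axis=1)
    msd = float(sq_from_origin.mean())

    angles = _turning_angles(traj)
    if angles.size:
        persistence = float(np.cos(angles).mean())
        mean_turn = float(np.degrees(angles).mean())
    else:
        persistence = math.nan
        mean_turn = math.nan

    path_len = float(kin.displacement_um.sum())
    net = float(np.linalg.norm(r[-1] - r[0]))
    straightness = net / path_len if path_len > 0 else math.nan

    com = r.mean(axis=0)
    gyration = float(np.sqrt(((r - com) ** 2).sum(axis=1).mean()))

    speed = kin.speed_um_per_frame
    arrest = float((speed < arrest_threshold).mean())

    if traj.areas is not None and np.isfinite(traj.areas).sum() >= 3:
        area_tail = traj.areas[1:]  # pair area at frame k with speed into k
        ok = np.isfinite(area_tail)
        coupling = _pearson(area_tail[ok], speed[ok])
    else:
        coupling = math.nan

    mean_speed = float(speed.mean())
    rel_change = (
        float(np.abs(np.diff(speed)).mean() / mean_speed)
        if mean_speed > 0 and len(speed) > 1
        else math.nan
    )

    steps = np.diff(r, axis=0)
    vxcorr = _pearson(steps[:, 0], steps[:, 1])

    mean_accel = (
        float(kin.acceleration_um_per_frame2.mean())
        if kin.acceleration_um_per_frame2.size
        else math.nan
    )

    return MotilityMetrics(
        msd=msd,
        directional_persistence=persistence,
        meandering_index=straightness,
        mean_turning_angle_deg=mean_turn,
        radius_of_gyration=gyration,
        arrest_coefficient=arrest,
        shape_motion_coupling=coupling,
        relative_motion_change=rel_change,
        velocity_cross_correlation=vxcorr,
        directionality_ratio=straightness,
        mean_speed=mean_speed,
        mean_acceleration=mean_accel,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        return math.nan
    dx, dy = x - x.mean(), y - y.mean()
    denom = np.sqrt((dx**2).sum() * (dy**2).sum())
    if denom == 0:
        return math.nan
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))


def sharp_turn_fraction(
    traj: Trajectory, threshold_deg: float = DEFAULT_SHARP_TURN_DEG
) -> float:
    """Fraction of turning events exceeding ``threshold_deg``.

    Flags abrupt directional reversals; NaN when the trajectory has no
    directed steps to turn between.
    """
    angles = _turning_angles(traj)
    if angles.size == 0:
        return math.nan
    return float((np.degrees(angles) > threshold_deg).mean())


def msd_lag(traj: Trajectory, max_lag: Optional[int] = None) -> np.ndarray:
    """Time-averaged MSD per lag (diagnostic for diffusive scaling).

    Entry ``tau-1`` is the mean of ‖r_{t+tau} − r_t‖² over all t; the
    from-origin scalar in :func:`motility_metrics` is the headline
    summary, this resolves the full curve for slope fitting.
    """
    r = traj.positions
    n = len(r)
    if max_lag is None:
        max_lag = n - 1
    out = np.empty(max_lag)
    for tau in range(1, max_lag + 1):
        d = r[tau:] - r[:-tau]
        out[tau - 1] = (d**2).sum(axis=1).mean()
    return out


# ----------------------------------------------------------------------
# static vs dynamic aggregation


def aggregate(
    tracks: Sequence[Trajectory],
    mode: str,
    arrest_threshold: float = DEFAULT_ARREST_THRESHOLD,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> pd.DataFrame:
    """Summaries over a cell population.

    ``dynamic``: one row per track, instantaneous values averaged over
    the track's lifespan (the twelve-metric profile). ``static``: one
    row per frame, instantaneous displacement/speed/acceleration
    averaged over the cells present at that frame.
    """
    if not tracks:
        raise ValueError("aggregate needs at least one trajectory")
    if mode == "dynamic":
        rows = []
        for tr in tracks:
            if len(tr) < 2:
                continue
            m = motility_metrics(tr, arrest_threshold, frame_interval_s)
            rows.append({"track_id": tr.track_id, **m.as_dict()})
        return pd.DataFrame(rows, columns=["track_id", *FIG_METRIC_ORDER])
    if mode == "static":
        acc: dict[int, dict[str, list]] = {}
        for tr in tracks:
            if len(tr) < 2:
                continue
            kin = kinematics(tr, frame_interval_s)
            for i, f in enumerate(tr.frames[1:]):
                d = acc.setdefault(int(f), {"disp": [], "speed": [], "accel": []})
                d["disp"].append(kin.displacement_um[i])
                d["speed"].append(kin.speed_um_per_frame[i])
                if i >= 1:
                    d["accel"].append(kin.acceleration_um_per_frame2[i - 1])
        rows = [
            {
                "frame": f,
                "n_cells": len(v["speed"]),
                "mean_displacement_um": float(np.mean(v["disp"])),
                "mean_speed_um_per_frame": float(np.mean(v["speed"])),
                "mean_acceleration_um_per_frame2": (
                    float(np.mean(v["accel"])) if v["accel"] else math.nan
                ),
            }
            for f, v in sorted(acc.items())
        ]
        return pd.DataFrame(rows)
    raise ValueError(f"mode must be 'static' or 'dynamic', got {mode!r}")
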