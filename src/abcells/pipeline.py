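"""Pipeline orchestration: staged runs, config, manifests, file outputs.

Stages mirror the package's two halves — simulate / track feed the
tracker side, analyse / stats the analysis side — and each stage reads
the previous stage's documented files and writes its own, together with
a manifest (config hash, seed, input checksums, package version) that
makes every output directory re-runnable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import DEFAULT_CALIBRATION_UM_PER_PX, Polygon
from .ingest import FrameDetections
from .motility import (
    DEFAULT_ARREST_THRESHOLD,
    DEFAULT_FRAME_INTERVAL_S,
    DEFAULT_MAX_GAP_FRAMES,
    DEFAULT_MAX_STEP_UM,
    Trajectory,
    aggregate,
)
from .stats import SeriesPanel, scan_tables, sliding_scan
from .synth import Brownian, Persistent, gen_scene
from .tracker import Tracker, TrackerConfig, evaluate_tracking

logger = logging.getLogger("abcells")

__all__ = ["PipelineConfig", "run_pipeline", "write_outputs"]


@dataclass
class PipelineConfig:
    """Flat configuration for the whole pipeline; YAML-overridable."""

    calibration_um_per_px: float = DEFAULT_CALIBRATION_UM_PER_PX
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    arrest_threshold_um_per_frame: float = DEFAULT_ARREST_THRESHOLD
    sharp_turn_deg: float = 90.0
    link_max_step_um: float = DEFAULT_MAX_STEP_UM
    link_max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES
    ma_window: int = 15
    test_window: int = 15
    n_permutations: int = 1000
    n_bootstrap: int = 10000
    alpha: float = 0.05
    seed: int = 0
    # tracker constants
    w_iou: float = 0.4
    w_dist: float = 0.3
    w_feat: float = 0.2
    w_area: float = 0.1
    base_gate_px: float = 50.0
    velocity_gate_gain: float = 2.0
    cost_max_stage1: float = 0.6
    cost_max_stage2: float = 0.8
    ewma_alpha: float = 0.3
    max_gap_frames: int = 30
    reid_similarity_min: float = 0.9
    split_iou_min: float = 0.2
    min_area_px2: float = 100.0
    # simulation defaults
    sim_n_cells: int = 20
    sim_frames: int = 100
    sim_motion: str = "brownian"  # brownian | persistent
    sim_sigma_px: float = 2.0
    sim_division_prob: float = 0.0
    sim_dropout_prob: float = 0.0
    sim_image_size: int = 1024
    # optional audit-trail outputs
    save_overlays: bool = False
    save_store: bool = False

    def tracker_config(self) -> TrackerConfig:
        return TrackerConfig(
            w_iou=self.w_iou,
            w_dist=self.w_dist,
            w_feat=self.w_feat,
            w_area=self.w_area,
            base_gate_px=self.base_gate_px,
            velocity_gate_gain=self.velocity_gate_gain,
            cost_max_stage1=self.cost_max_stage1,
            cost_max_stage2=self.cost_max_stage2,
            ewma_alpha=self.ewma_alpha,
            max_gap_frames=self.max_gap_frames,
            reid_similarity_min=self.reid_similarity_min,
            split_iou_min=self.split_iou_min,
            min_area_px2=self.min_area_px2,
        )

    @classmethod
    def load(cls, path: Optional[str] = None, **overrides) -> "PipelineConfig":
        data: dict = {}
        if path is not None:
            data.update(yaml.safe_load(Path(path).read_text()) or {})
        data.update({k: v for k, v in overrides.items() if v is not None})
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    def dump(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(out: Path, cfg: PipelineConfig, stage: str,
                   inputs: list[Path]) -> None:
    cfg_text = yaml.safe_dump(asdict(cfg), sort_keys=True)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "inputs": {p.name: _checksum(p) for p in inputs if p.exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(cfg_text)


def write_outputs(tables: dict[str, pd.DataFrame], out: Path) -> list[Path]:
    """Write each named table as CSV (header always present)."""
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    return written


def write_store(tables: dict[str, pd.DataFrame], path: Path) -> Path:
    """Mirror the CSV tables into a single-file SQLite store (audit trail)."""
    import sqlite3

    with sqlite3.connect(path) as con:
        for name, df in tables.items():
            df.to_sql(name, con, if_exists="replace", index=False)
    return path


def write_overlays(track_table: pd.DataFrame, image_size: tuple[int, int],
                   out: Path) -> list[Path]:
    """One PNG per frame with id-labeled track contours."""
    from PIL import Image, ImageDraw

    out.mkdir(parents=True, exist_ok=True)
    written = []
    for frame, g in track_table.groupby("frame"):
        im = Image.new("RGB", image_size, (0, 0, 0))
        draw = ImageDraw.Draw(im)
        for row in g.itertuples():
            verts = [tuple(v) for v in json.loads(row.polygon)]
            draw.polygon(verts, outline=(0, 255, 0))
            draw.text(
                (row.centroid_x_px, row.centroid_y_px),
                str(int(row.track_id)),
                fill=(255, 255, 0),
            )
        p = out / f"overlay_{int(frame):05d}.png"
        im.save(p)
        written.append(p)
    return written


# ----------------------------------------------------------------------
# stages


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    model = (
        Brownian(cfg.sim_sigma_px)
        if cfg.sim_motion == "brownian"
        else Persistent(cfg.sim_sigma_px, 0.7)
    )
    frames, truth = gen_scene(
        n_cells=cfg.sim_n_cells,
        model=model,
        T=cfg.sim_frames,
        division_prob_per_frame=cfg.sim_division_prob,
        dropout_prob=cfg.sim_dropout_prob,
        image_size=(cfg.sim_image_size, cfg.sim_image_size),
        seed=cfg.seed,
    )
    det_path = out / "detections.jsonl"
    with det_path.open("w") as fh:
        for fd in frames:
            fh.write(fd.to_json() + "\n")
    truth_obj = {
        "lineage": [
            {"frame": f, "parent": p, "children": list(ch)}
            for f, p, ch in truth.lineage
        ],
        "dropouts": [{"frame": f, "id": i} for f, i in truth.dropouts],
        "polygons": {
            str(f): {str(i): poly.vertices.tolist() for i, poly in objs.items()}
            for f, objs in truth.polygons.items()
        },
    }
    (out / "truth.json").write_text(json.dumps(truth_obj))
    logger.info("simulated %d frames, %d initial cells", cfg.sim_frames, cfg.sim_n_cells)


def _load_detections(path: Path) -> list[FrameDetections]:
    return [FrameDetections.from_json(line) for line in path.read_text().splitlines()]


def _stage_track(cfg: PipelineConfig, out: Path, det_path: Path) -> None:
    if not det_path.exists():
        raise FileNotFoundError(f"missing detections file: {det_path}")
    frames = _load_detections(det_path)
    tracker = Tracker(cfg.tracker_config())
    table = tracker.run(frames)
    tables = {
        "tracks": table,
        "frame_metrics": tracker.metrics_table(),
        "lineage_events": tracker.lineage_table(),
    }
    write_outputs(tables, out)
    if cfg.save_store:
        write_store(tables, out / "tracks.sqlite")
    if cfg.save_overlays:
        write_overlays(
            table, (cfg.sim_image_size, cfg.sim_image_size), out / "overlays"
        )


def _stage_analyse(cfg: PipelineConfig, out: Path, tracks_path: Path) -> None:
    if not tracks_path.exists():
        raise FileNotFoundError(f"missing track table: {tracks_path}")
    table = pd.read_csv(tracks_path)
    calib = cfg.calibration_um_per_px
    trajs = []
    for tid, g in table.groupby("track_id"):
        g = g.sort_values("frame")
        if len(g) < 2:
            continue
        trajs.append(
            Trajectory(
                track_id=int(tid),
                frames=g["frame"].to_numpy(),
                positions=g[["centroid_x_px", "centroid_y_px"]].to_numpy() * calib,
                areas=g["area_px2"].to_numpy() * calib**2,
            )
        )
    if not trajs:
        raise ValueError("no trajectory with >= 2 points in track table")
    traj_rows = []
    for tr in trajs:
        for i in range(len(tr)):
            traj_rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": int(tr.frames[i]),
                    "x_um": tr.positions[i, 0],
                    "y_um": tr.positions[i, 1],
                    "area_um2": tr.areas[i] if tr.areas is not None else np.nan,
                    "interpolated": bool(tr.interpolated[i]),
                }
            )
    write_outputs(
        {
            "trajectories": pd.DataFrame(traj_rows),
            "track_metrics": aggregate(
                trajs, "dynamic", cfg.arrest_threshold_um_per_frame,
                cfg.frame_interval_s,
            ),
            "frame_aggregates": aggregate(
                trajs, "static", cfg.arrest_threshold_um_per_frame,
                cfg.frame_interval_s,
            ),
        },
        out,
    )


def _stage_stats(cfg: PipelineConfig, out: Path, panel_path: Path) -> None:
    if not panel_path.exists():
        raise FileNotFoundError(f"missing panel file: {panel_path}")
    panel = SeriesPanel.from_long(pd.read_csv(panel_path))
    results = sliding_scan(
        panel,
        ma_w=cfg.ma_window,
        window_w=cfg.test_window,
        n_permutations=cfg.n_permutations,
        alpha=cfg.alpha,
        seed=cfg.seed,
    )
    windows, pairs = scan_tables(results, panel.series_ids)
    write_outputs({"windows": windows, "pairwise_significance": pairs}, out)


def _stage_evaluate(cfg: PipelineConfig, out: Path, sim_dir: Path,
                    track_dir: Path) -> None:
    truth_path = sim_dir / "truth.json"
    tracks_path = track_dir / "tracks.csv"
    for p in (truth_path, tracks_path):
        if not p.exists():
            raise FileNotFoundError(f"missing input: {p}")
    from .synth import SceneTruth
    from .tracker import LineageEvent

    obj = json.loads(truth_path.read_text())
    truth = SceneTruth()
    for f, objs in obj["polygons"].items():
        truth.polygons[int(f)] = {
            int(i): Polygon(v) for i, v in objs.items()
        }
    truth.lineage = [
        (e["frame"], e["parent"], tuple(e["children"])) for e in obj["lineage"]
    ]
    events = []
    lin_path = track_dir / "lineage_events.csv"
    if lin_path.exists():
        lin = pd.read_csv(lin_path)
        for row in lin.itertuples():
            events.append(
                LineageEvent(
                    frame=int(row.frame),
                    parent_id=int(row.parent_id),
                    child_ids=tuple(int(x) for x in str(row.child_ids).split(";")),
                    kind=row.kind,
                )
            )
    table = pd.read_csv(tracks_path)
    metrics = evaluate_tracking(table, truth, events)
    (out / "evaluation.json").write_text(json.dumps(metrics, indent=2))


STAGES = ("simulate", "track", "analyse", "stats", "evaluate")


def run_pipeline(
    stage: str,
    cfg: PipelineConfig,
    out_dir: str,
    detections: Optional[str] = None,
    tracks: Optional[str] = None,
    panel: Optional[str] = None,
    sim_dir: Optional[str] = None,
    track_dir: Optional[str] = None,
) -> Path:
    """Run one pipeline stage into ``out_dir``; returns the output path."""
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: list[Path] = []
    if stage == "simulate":
        _stage_simulate(cfg, out)
    elif stage == "track":
        det_path = Path(detections) if detections else out.parent / "simulate" / "detections.jsonl"
        inputs.append(det_path)
        _stage_track(cfg, out, det_path)
    elif stage == "analyse":
        tr_path = Path(tracks) if tracks else out.parent / "track" / "tracks.csv"
        inputs.append(tr_path)
        _stage_analyse(cfg, out, tr_path)
    elif stage == "stats":
        panel_path = Path(panel) if panel else out.parent / "analyse" / "panel.csv"
        inputs.append(panel_path)
        _stage_stats(cfg, out, panel_path)
    elif stage == "evaluate":
        sd = Path(sim_dir) if sim_dir else out.parent / "simulate"
        td = Path(track_dir) if track_dir else out.parent / "track"
        inputs += [sd / "truth.json", td / "tracks.csv"]
        _stage_evaluate(cfg, out, sd, td)
    write_manifest(out, cfg, stage, inputs)
    return out
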