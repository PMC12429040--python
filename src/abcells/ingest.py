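"""Detection input: YOLO-seg text, classical mask segmentation, tile stitching.

The tracker is detector-agnostic; any source able to emit per-frame
polygon sets can feed it. This module covers the two standard sources —
normalized-polygon text files as written by YOLO segmentation exports,
and a classical adaptive-threshold pipeline for plain grayscale frames —
plus the stitching step that reconciles detections from overlapping
image tiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology
from shapely.geometry import MultiPolygon as _MultiPolygon
from shapely.ops import unary_union

from .geometry import Polygon, polygon_iou

__all__ = [
    "Detection",
    "FrameDetections",
    "YoloParseError",
    "read_yolo_polygons",
    "write_yolo_polygons",
    "segment_classical",
    "tile_stitch",
]

DEFAULT_MIN_AREA_PX2 = 100.0  # artifact filter: components below this are noise


class YoloParseError(ValueError):
    """Malformed YOLO segmentation line (odd coords, out-of-range values)."""


@dataclass
class Detection:
    """One segmented cell footprint in one frame."""

    frame: int
    poly: Polygon
    confidence: Optional[float] = None
    class_id: int = 0
    source: str = ""


@dataclass
class FrameDetections:
    """Deduplicated detections of a single frame."""

    frame: int
    detections: list[Detection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.detections)

    def polygons(self) -> list[Polygon]:
        return [d.poly for d in self.detections]

    def to_json(self) -> str:
        return json.dumps(
            {
                "frame": self.frame,
                "detections": [
                    {
                        "class_id": d.class_id,
                        "confidence": d.confidence,
                        "source": d.source,
                        "vertices_px": d.poly.vertices.tolist(),
                    }
                    for d in self.detections
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FrameDetections":
        obj = json.loads(text)
        dets = [
            Detection(
                frame=obj["frame"],
                poly=Polygon(d["vertices_px"]),
                confidence=d.get("confidence"),
                class_id=d.get("class_id", 0),
                source=d.get("source", ""),
            )
            for d in obj["detections"]
        ]
        return cls(frame=obj["frame"], detections=dets)


def read_yolo_polygons(
    path: Union[str, Path],
    image_size: tuple[int, int],
    frame: int = 0,
) -> list[Detection]:
    """Parse a YOLO segmentation text file into pixel-space detections.

    Each line is ``class_id x1 y1 x2 y2 ...`` with coordinates normalized
    to [0, 1]; they are scaled by the image size (W, H). An empty file
    yields an empty list; malformed lines raise :class:`YoloParseError`
    naming the line number.
    """
    W, H = image_size
    path = Path(path)
    out: list[Detection] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        try:
            class_id = int(parts[0])
            coords = np.array([float(p) for p in parts[1:]])
        except ValueError as exc:
            raise YoloParseError(f"{path}:{lineno}: non-numeric token") from exc
        if coords.size < 6 or coords.size % 2 != 0:
            raise YoloParseError(
                f"{path}:{lineno}: expected an even count >= 6 of "
                f"coordinates, got {coords.size}"
            )
        if coords.min() < 0.0 or coords.max() > 1.0:
            raise YoloParseError(
                f"{path}:{lineno}: normalized coordinate outside [0, 1]"
            )
        xy = coords.reshape(-1, 2) * np.array([W, H])
        out.append(
            Detection(frame=frame, poly=Polygon(xy), class_id=class_id,
                      source=str(path))
        )
    return out


def write_yolo_polygons(
    detections: Sequence[Detection],
    path: Union[str, Path],
    image_size: tuple[int, int],
) -> None:
    """Inverse of :func:`read_yolo_polygons` (round-trip safe)."""
    W, H = image_size
    lines = []
    for d in detections:
        norm = d.poly.vertices / np.array([W, H])
        coords = " ".join(f"{v:.9f}" for v in norm.ravel())
        lines.append(f"{d.class_id} {coords}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def flatfield_correct(image: np.ndarray, sigma: Optional[float] = None) -> np.ndarray:
    """Divide out a heavily smoothed background estimate (uneven illumination)."""
    img = np.asarray(image, dtype=float)
    if sigma is None:
        sigma = min(img.shape) / 8.0
    background = ndi.gaussian_filter(img, sigma=sigma)
    background = np.where(background == 0, 1.0, background)
    return img / background


def segment_classical(
    image: np.ndarray,
    min_area_px2: float = DEFAULT_MIN_AREA_PX2,
    block_size: int = 51,
    closing_radius: int = 2,
    flatfield: bool = False,
    invert: bool = False,
    offset_frac: float = 0.01,
) -> list[Polygon]:
    """Classical mask pipeline: adaptive threshold -> closing -> components.

    Connected components with pixel area strictly below ``min_area_px2``
    are discarded as artifacts (a component of exactly the threshold area
    is kept). ``invert`` selects dark-on-bright objects. ``offset_frac``
    demands that much of the image's intensity range in local contrast
    before a pixel counts as foreground, suppressing flat-field noise;
    being range-relative it keeps the output invariant to additive
    intensity offsets.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={img.ndim}")
    if flatfield:
        img = flatfield_correct(img)
    offset = offset_frac * (img.max() - img.min())
    thresh = filters.threshold_local(img, block_size=block_size, method="gaussian")
    binary = img < thresh - offset if invert else img > thresh + offset
    binary = morphology.closing(binary, morphology.disk(closing_radius))
    labels, _ = ndi.label(binary)
    polygons: list[Polygon] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px2:
            continue
        poly = _region_to_polygon(labels == region.label)
        if poly is not None:
            polygons.append(poly)
    return polygons


def mask_to_polygons(
    mask: np.ndarray, min_area_px2: float = DEFAULT_MIN_AREA_PX2
) -> list[Polygon]:
    """Polygonize a labeled or boolean mask, dropping sub-threshold components."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if mask.dtype == bool:
        labels, _ = ndi.label(mask)
    else:
        labels = mask.astype(int)
    polygons = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px2:
            continue
        poly = _region_to_polygon(labels == region.label)
        if poly is not None:
            polygons.append(poly)
    return polygons


def _region_to_polygon(region_mask: np.ndarray) -> Optional[Polygon]:
    """Trace the outer contour of one connected component."""
    padded = np.pad(region_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)  # outer boundary is the longest
    # (row, col) -> (x, y), undo the pad offset
    xy = np.c_[contour[:, 1] - 1.0, contour[:, 0] - 1.0]
    if len(xy) > 3 and np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    if len(xy) < 3:
        return None
    try:
        return Polygon(xy)
    except ValueError:
        return None


def _shapely_to_polygon(geom) -> Polygon:
    if isinstance(geom, _MultiPolygon):
        geom = max(geom.geoms, key=lambda g: g.area)
    xy = np.asarray(geom.exterior.coords)[:-1]
    return Polygon(xy)


def tile_stitch(
    image_size: tuple[int, int],
    tiles: Sequence[tuple[tuple[float, float], Sequence[Detection]]],
    dup_iou: float = 0.8,
    merge_iou: float = 0.3,
    frame: int = 0,
) -> FrameDetections:
    """Combine tile-local detections into one global per-frame polygon set.

    Detections are translated by their tile offsets; near-identical pairs
    (IoU >= ``dup_iou``) are greedily suppressed keeping the higher
    confidence (ties: larger area, then lower tile index), and partially
    overlapping pairs from different tiles (``merge_iou`` <= IoU <
    ``dup_iou``) are union-merged — the typical seam case where each tile
    saw half of a cell.
    """
    W, H = image_size
    pool: list[tuple[Detection, int]] = []  # (global detection, tile index)
    for tile_idx, (offset, dets) in enumerate(tiles):
        ox, oy = offset
        if not (0 <= ox <= W and 0 <= oy <= H):
            raise ValueError(f"tile offset {offset} outside image {image_size}")
        for d in dets:
            pool.append(
                (
                    Detection(
                        frame=frame,
                        poly=d.poly.translated(ox, oy),
                        confidence=d.confidence,
                        class_id=d.class_id,
                        source=d.source or f"tile{tile_idx}",
                    ),
                    tile_idx,
                )
            )

    # greedy duplicate suppression, strongest detection first
    def _rank(item):
        d, idx = item
        conf = d.confidence if d.confidence is not None else 0.0
        return (-conf, -d.poly.area_px2(), idx)

    pool.sort(key=_rank)
    kept: list[tuple[Detection, int]] = []
    for cand, idx in pool:
        if all(polygon_iou(cand.poly, k.poly) < dup_iou for k, _ in kept):
            kept.append((cand, idx))

    # union-merge cross-tile fragments
    merged = True
    while merged:
        merged = False
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                di, ti = kept[i]
                dj, tj = kept[j]
                if ti == tj:
                    continue
                iou = polygon_iou(di.poly, dj.poly)
                if merge_iou <= iou < dup_iou:
                    union = unary_union(
                        [di.poly.to_shapely(), dj.poly.to_shapely()]
                    )
                    conf = max(
                        di.confidence or 0.0, dj.confidence or 0.0
                    ) or None
                    kept[i] = (
                        Detection(
                            frame=frame,
                            poly=_shapely_to_polygon(union),
                            confidence=conf,
                            class_id=di.class_id,
                            source=f"{di.source}+{dj.source}",
                        ),
                        ti,
                    )
                    del kept[j]
                    merged = True
                    break
            if merged:
                break

    return FrameDetections(frame=frame, detections=[d for d, _ in kept])
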