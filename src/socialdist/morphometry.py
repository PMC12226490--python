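"""Body-size estimation from outline polygons.

A mouse's size is estimated as the area of a polygon drawn around its body
in a representative frame, converted to mm² with the arena calibration.
Polygons are consumed from a vertex CSV (``animal_id, vertex_order, x_px,
y_px``); drawing them is outside this package.  A synthetic mouse-outline
generator is provided for tests and simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

from .trajectory_io import ArenaCalibration


@dataclass(frozen=True)
class BodyPolygon:
    animal_id: str
    vertices_px: np.ndarray  # (n, 2)
    area_mm2: float
    frame_index: int = 0


def shoelace_area_px2(vertices: np.ndarray) -> float:
    """Absolute shoelace (surveyor's) area of a polygon in px²."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def polygon_area(
    vertices: Sequence[Sequence[float]] | np.ndarray, calibration: ArenaCalibration
) -> float:
    """Area of a simple polygon in mm² (shoelace x mm_per_pixel²).

    Orientation-independent; rejects polygons with fewer than three
    vertices or with self-intersections.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    if not np.all(np.isfinite(v)):
        raise ValueError("polygon vertices must be finite")
    if not _ShapelyPolygon(v).is_simple:
        raise ValueError("polygon is self-intersecting")
    area_px2 = shoelace_area_px2(v)
    if area_px2 <= 0:
        raise ValueError("polygon has zero area (degenerate vertices)")
    return area_px2 * calibration.mm_per_pixel**2


def mouse_polygon(
    center_px: tuple[float, float] = (240.0, 135.0),
    length_px: float = 110.0,
    width_px: float = 45.0,
    heading_rad: float = 0.0,
    n_points: int = 24,
) -> np.ndarray:
    """Synthetic mouse body outline: a tapered ellipse (narrow at the nose).

    Returns an (n_points, 2) vertex array in pixels, suitable as a
    stand-in for a manually drawn body polygon.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    # Taper: half-width shrinks toward the +x (nose) end.
    a, b = length_px / 2.0, width_px / 2.0
    x = a * np.cos(t)
    y = b * np.sin(t) * (1.0 - 0.35 * np.cos(t))
    c, s = np.cos(heading_rad), np.sin(heading_rad)
    pts = np.column_stack([c * x - s * y, s * x + c * y])
    return pts + np.asarray(center_px, dtype=float)


def read_polygon_csv(
    path: str | Path, calibration: ArenaCalibration
) -> list[BodyPolygon]:
    """Read per-animal outline polygons from a vertex CSV and compute areas.

    Expected columns: ``animal_id, vertex_order, x_px, y_px`` (and
    optionally ``frame_index``).
    """
    df = pd.read_csv(path)
    required = {"animal_id", "vertex_order", "x_px", "y_px"}
    if not required <= set(df.columns):
        raise ValueError(f"polygon CSV must have columns {sorted(required)}")
    out = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("vertex_order")
        verts = grp[["x_px", "y_px"]].to_numpy(dtype=float)
        frame = int(grp["frame_index"].iloc[0]) if "frame_index" in grp else 0
        out.append(
            BodyPolygon(
                animal_id=str(animal_id),
                vertices_px=verts,
                area_mm2=polygon_area(verts, calibration),
                frame_index=frame,
            )
        )
    return out


def area_table(polygons: Sequence[BodyPolygon]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [p.animal_id for p in polygons],
            "area_mm2": [p.area_mm2 for p in polygons],
        }
    )
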