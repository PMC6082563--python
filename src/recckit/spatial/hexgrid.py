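"""Hexagonal tessellation of a planar region and point-to-tile assignment.

Tiles are regular hexagons addressed by axial coordinates ``(aq, ar)``.
Assignment is exact and O(1) per point via fractional axial coordinates
and cube rounding; boundary ties resolve deterministically through the
rounding rule (implementation-defined but reproducible).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence, Tuple, Union

import numpy as np
from shapely.geometry import Polygon, box

from ..core import CountVector, PointEvent

__all__ = ["HexGrid", "build_hex_grid", "assign_points_to_hexes", "hex_polygon"]

logger = logging.getLogger(__name__)

SQRT3 = math.sqrt(3.0)

Bbox = Tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)


def hex_area(side: float) -> float:
    """Area of a regular hexagon of the given edge length."""
    return 1.5 * SQRT3 * side * side


@dataclass(frozen=True)
class HexGrid:
    """A finite set of regular hexagons covering a rectangle.

    ``axials`` lists the axial coordinates of every tile whose hexagon
    has positive-area overlap with ``bbox``; together they cover the
    rectangle without overlaps.
    """

    origin: Tuple[float, float]
    side: float
    orientation: str
    bbox: Bbox
    axials: Tuple[Tuple[int, int], ...]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.axials)})

    @property
    def n_tiles(self) -> int:
        return len(self.axials)

    @property
    def tile_area(self) -> float:
        return hex_area(self.side)

    def centers(self) -> np.ndarray:
        """(n_tiles, 2) array of tile centre coordinates."""
        aq = np.array([a[0] for a in self.axials], dtype=float)
        ar = np.array([a[1] for a in self.axials], dtype=float)
        return np.column_stack(_axial_to_xy(aq, ar, self.origin, self.side, self.orientation))


def _axial_to_xy(aq, ar, origin, side, orientation):
    x0, y0 = origin
    if orientation == "flat":
        cx = x0 + 1.5 * side * aq
        cy = y0 + SQRT3 * side * (ar + aq / 2.0)
    elif orientation == "pointy":
        cx = x0 + SQRT3 * side * (aq + ar / 2.0)
        cy = y0 + 1.5 * side * ar
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")
    return cx, cy


def _xy_to_fractional_axial(x, y, origin, side, orientation):
    x0, y0 = origin
    dx = np.asarray(x, dtype=float) - x0
    dy = np.asarray(y, dtype=float) - y0
    if orientation == "flat":
        qf = (2.0 / 3.0) * dx / side
        rf = (-dx / 3.0 + SQRT3 / 3.0 * dy) / side
    elif orientation == "pointy":
        qf = (SQRT3 / 3.0 * dx - dy / 3.0) / side
        rf = (2.0 / 3.0) * dy / side
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")
    return qf, rf


def _cube_round(qf, rf):
    """Round fractional axial coordinates to the containing hexagon."""
    sf = -qf - rf
    aq = np.rint(qf)
    ar = np.rint(rf)
    asv = np.rint(sf)
    dq = np.abs(aq - qf)
    dr = np.abs(ar - rf)
    ds = np.abs(asv - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    aq = np.where(fix_q, -ar - asv, aq)
    ar = np.where(fix_r, -aq - asv, ar)
    return aq.astype(np.int64), ar.astype(np.int64)


def hex_polygon(grid: HexGrid, axial: Tuple[int, int]) -> Polygon:
    """Shapely polygon of one tile (vertices at the six corner angles)."""
    cx, cy = _axial_to_xy(float(axial[0]), float(axial[1]), grid.origin, grid.side,
                          grid.orientation)
    start = 0.0 if grid.orientation == "flat" else math.pi / 6.0
    angles = start + np.arange(6) * math.pi / 3.0
    return Polygon(np.column_stack([cx + grid.side * np.cos(angles),
                                    cy + grid.side * np.sin(angles)]))


def build_hex_grid(bbox: Bbox, side: float = 40.0, orientation: str = "flat") -> HexGrid:
    """Tessellate a rectangle with regular hexagons of the given side.

    The grid origin is the lower-left corner of ``bbox``; every hexagon
    with positive-area overlap with the rectangle is retained, so the
    tiles jointly cover it with no overlaps and the tile count is about
    ``area(bbox) / (1.5 * sqrt(3) * side**2)`` plus a boundary ring.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    xmin, ymin, xmax, ymax = map(float, bbox)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("bbox must be non-degenerate")
    origin = (xmin, ymin)
    rect = box(xmin, ymin, xmax, ymax)

    # candidate axial range: tile centres within one circumradius of bbox
    pad = 2.0 * side
    corners_x = np.array([xmin - pad, xmax + pad, xmin - pad, xmax + pad])
    corners_y = np.array([ymin - pad, ymin - pad, ymax + pad, ymax + pad])
    qf, rf = _xy_to_fractional_axial(corners_x, corners_y, origin, side, orientation)
    q_lo, q_hi = int(math.floor(qf.min())) - 2, int(math.ceil(qf.max())) + 2
    proto = HexGrid(origin, side, orientation, bbox, ())
    axials = []
    for aq in range(q_lo, q_hi + 1):
        # exact ar range putting the tile centre within the padded bbox
        if orientation == "flat":
            r_lo = math.floor((ymin - pad - ymin) / (SQRT3 * side) - aq / 2.0) - 1
            r_hi = math.ceil((ymax + pad - ymin) / (SQRT3 * side) - aq / 2.0) + 1
        else:
            r_lo = math.floor((ymin - pad - ymin) / (1.5 * side)) - 1
            r_hi = math.ceil((ymax + pad - ymin) / (1.5 * side)) + 1
        for ar in range(int(r_lo), int(r_hi) + 1):
            cx, cy = _axial_to_xy(float(aq), float(ar), origin, side, orientation)
            if not (xmin - pad <= cx <= xmax + pad and ymin - pad <= cy <= ymax + pad):
                continue
            poly = hex_polygon(proto, (aq, ar))
            if poly.intersects(rect) and poly.intersection(rect).area > 1e-9:
                axials.append((aq, ar))
    axials.sort()
    return HexGrid(origin, side, orientation, bbox, tuple(axials))


def _event_xy(events) -> np.ndarray:
    if isinstance(events, np.ndarray):
        arr = np.asarray(events, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError("event array must have shape (n, 2)")
        return arr[:, :2]
    return np.array([(e.x, e.y) for e in events], dtype=float).reshape(-1, 2)


def assign_points_to_hexes(
    events: Union[Sequence[PointEvent], np.ndarray],
    grid: HexGrid,
    strict: bool = False,
    window_years: float = 1.0,
) -> CountVector:
    """Count events per tile.

    Every event maps to exactly one tile; events falling outside the
    grid are dropped with a logged warning, or raise in strict mode.
    """
    xy = _event_xy(events)
    counts = np.zeros(grid.n_tiles, dtype=np.int64)
    if xy.shape[0]:
        if not np.all(np.isfinite(xy)):
            raise ValueError("event coordinates must be finite")
        qf, rf = _xy_to_fractional_axial(xy[:, 0], xy[:, 1], grid.origin, grid.side,
                                         grid.orientation)
        aq, ar = _cube_round(qf, rf)
        n_dropped = 0
        for a, r in zip(aq.tolist(), ar.tolist()):
            idx = grid._index.get((a, r))
            if idx is None:
                if strict:
                    raise ValueError(f"event assigned outside the grid (axial {(a, r)})")
                n_dropped += 1
            else:
                counts[idx] += 1
        if n_dropped:
            logger.warning("dropped %d event(s) outside the grid", n_dropped)
    return CountVector(counts, unit_ids=list(grid.axials), window_years=window_years)
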