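"""Synthetic point patterns and count vectors for testing the pipeline.

Built-in scenarios reproduce the statistical regimes the method is
designed for: zero-inflated heavy-tailed urban counts, near-uniform
motorway counts, a 3-group motorway regime, and a CSR point pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from shapely.geometry import Point

from . import data
from .core import CountVector, MixtureDistribution, PointEvent
from .mixture import simulate_counts
from .spatial.hexgrid import HexGrid, build_hex_grid, hex_polygon

__all__ = ["ScenarioSpec", "gen_uniform_points", "gen_scenario", "scenario", "SCENARIOS"]

Bbox = Tuple[float, float, float, float]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named synthetic regime: a true mixture plus a domain to realise it on.

    ``hex_domain`` is an optional ``(bbox, side)`` pair; when present
    the per-unit events are also scattered uniformly inside their tiles
    to produce a point pattern.
    """

    name: str
    truth: MixtureDistribution
    n_units: int
    window_years: float = 1.0
    hex_domain: Optional[Tuple[Bbox, float]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be at least 1")


def gen_uniform_points(n: int, bbox: Bbox, seed=None):
    """``n`` i.i.d. uniform points in a rectangle (the CSR null)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    xmin, ymin, xmax, ymax = map(float, bbox)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("bbox must be non-degenerate")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = rng.uniform(xmin, xmax, n)
    y = rng.uniform(ymin, ymax, n)
    return [PointEvent(float(a), float(b)) for a, b in zip(x, y)]


def _scatter_in_hex(grid: HexGrid, axial, count: int, rng) -> list:
    """Rejection-sample ``count`` uniform points inside one hexagon."""
    poly = hex_polygon(grid, axial)
    xmin, ymin, xmax, ymax = poly.bounds
    pts = []
    while len(pts) < count:
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if poly.covers(Point(x, y)):
            pts.append(PointEvent(x, y))
    return pts


def gen_scenario(spec: ScenarioSpec, seed=None):
    """Realise a scenario: per-unit counts, plus a point pattern for hex domains.

    Returns ``(CountVector, points_or_None)``.  ``seed`` overrides the
    seed stored in the spec.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.hex_domain is not None:
        bbox, side = spec.hex_domain
        grid = build_hex_grid(bbox, side=side)
        n_units = grid.n_tiles
        counts = simulate_counts(spec.truth, n_units, seed=rng,
                                 window_years=spec.window_years)
        counts = CountVector(counts.counts, unit_ids=list(grid.axials),
                             window_years=spec.window_years)
        points = []
        for axial, c in zip(grid.axials, counts.counts):
            if c:
                points.extend(_scatter_in_hex(grid, axial, int(c), rng))
        return counts, points
    counts = simulate_counts(spec.truth, spec.n_units, seed=rng,
                             window_years=spec.window_years)
    return counts, None


def _uniform_points_truth(rate: float) -> MixtureDistribution:
    return MixtureDistribution((1.0,), (rate,))


SCENARIOS = {
    # zero-inflated, heavy-tailed urban regime on a large grid
    "london_table4": ScenarioSpec(
        name="london_table4",
        truth=data.URBAN_SEVERE_MIXTURE,
        n_units=29_600,
        window_years=10.0,
    ),
    # near-uniform motorway regime: one rate across 242 half-km segments
    "puebla_uniform": ScenarioSpec(
        name="puebla_uniform",
        truth=MixtureDistribution((1.0,), (data.PUEBLA_UNIFORM_RATE,), window_years=2.0),
        n_units=242,
        window_years=2.0,
    ),
    # 3-group motorway regime: 62.5 km road in half-km segments
    "pachuca_3group": ScenarioSpec(
        name="pachuca_3group",
        truth=data.PACHUCA_3GROUP_MIXTURE,
        n_units=125,
        window_years=2.0,
    ),
    # homogeneous spatial regime on a 1 km square, hex side 40 m
    "csr_null": ScenarioSpec(
        name="csr_null",
        truth=_uniform_points_truth(1.0),
        n_units=1,  # derived from the hex domain at generation time
        hex_domain=((0.0, 0.0, 1000.0, 1000.0), 40.0),
    ),
}


def scenario(name: str, seed: Optional[int] = None, **overrides) -> ScenarioSpec:
    """Look up a built-in scenario, optionally overriding fields."""
    try:
        spec = SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
    if seed is not None:
        overrides["seed"] = seed
    return replace(spec, **overrides) if overrides else spec
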