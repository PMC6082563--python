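"""Fixed-length segmentation of a linear domain (kilometre-post events).

Segments are half-open ``[a, b)`` with the final segment closed at the
road end, indexed from 0; positions are kilometre posts measured from
the road origin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..core import CountVector

__all__ = ["LinearPartition", "segment_road"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinearPartition:
    """Partition of a road of ``road_length`` km into fixed segments."""

    road_length: float  # kilometres
    segment_length: float = 500.0  # metres

    def __post_init__(self) -> None:
        if self.road_length <= 0:
            raise ValueError("road_length must be positive")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")

    @property
    def n_segments(self) -> int:
        return int(math.ceil(self.road_length * 1000.0 / self.segment_length))


def segment_road(
    positions: Sequence[float],
    road_length: float,
    segment_length: float = 500.0,
    strict: bool = False,
    window_years: float = 1.0,
) -> CountVector:
    """Bin kilometre-post positions into fixed-length segments.

    Parameters
    ----------
    positions : sequence of float
        Event positions in kilometres from the road origin.
    road_length : float
        Road length in kilometres.
    segment_length : float
        Segment length in metres (default 500).

    Out-of-range positions are dropped with a logged warning, or raise
    in strict mode.  A position exactly at the road end falls in the
    last segment.
    """
    part = LinearPartition(road_length, segment_length)
    n = part.n_segments
    pos = np.asarray(positions, dtype=float)
    counts = np.zeros(n, dtype=np.int64)
    if pos.size:
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        in_range = (pos >= 0.0) & (pos <= road_length)
        n_dropped = int((~in_range).sum())
        if n_dropped:
            if strict:
                raise ValueError(f"{n_dropped} position(s) outside [0, {road_length}] km")
            logger.warning("dropped %d position(s) outside the road", n_dropped)
        idx = np.floor(pos[in_range] * 1000.0 / segment_length).astype(np.int64)
        np.clip(idx, 0, n - 1, out=idx)  # road-end positions close the last segment
        np.add.at(counts, idx, 1)
    return CountVector(counts, window_years=window_years)
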