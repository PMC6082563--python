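"""Core domain types shared across the toolkit.

All coordinates are assumed to be planar, in metres (pre-projected);
no CRS handling is performed anywhere in the package.  Rates are always
expressed per unit per observation window; conversion to other time
scales is an explicit operation (:meth:`MixtureDistribution.scaled`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "PointEvent",
    "CountVector",
    "MixtureDistribution",
    "FitResult",
    "GofReport",
    "LorenzCurve",
    "ConcentrationReport",
    "ReccCI",
]


class PointEvent(NamedTuple):
    """A single event located in the plane.

    ``x``/``y`` are planar coordinates in metres.  ``severity`` is an
    optional categorical label (e.g. ``fatal``/``serious``/``slight``),
    ``t`` an optional timestamp; neither is used by the core math.
    """

    x: float
    y: float
    severity: Optional[str] = None
    t: Optional[str] = None


@dataclass
class CountVector:
    """Per-unit non-negative event counts after discretisation.

    Parameters
    ----------
    counts : array-like of int
        One non-negative count per unit, ``H_i``.
    unit_ids : sequence, optional
        Ordered unit identifiers (hex axial coordinates or segment
        indices).  Defaults to ``0..N-1``.
    window_years : float
        Length of the observation window the counts were collected
        over.  Metadata only; never applied implicitly.
    """

    counts: np.ndarray
    unit_ids: Optional[Sequence] = None
    window_years: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.unit_ids is None:
            self.unit_ids = list(range(self.counts.size))
        elif len(self.unit_ids) != self.counts.size:
            raise ValueError("unit_ids and counts must have equal length")
        if not self.window_years > 0:
            raise ValueError("window_years must be positive")

    @property
    def n_units(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.n_units


@dataclass(frozen=True)
class MixtureDistribution:
    """A finite Poisson mixture: group weights ``q`` and rates ``lam``.

    Invariants: weights are positive and sum to one (within 1e-9),
    rates are non-negative and strictly increasing.  Rates are per unit
    per observation window of ``window_years``.
    """

    q: tuple
    lam: tuple
    window_years: float = 1.0

    def __post_init__(self) -> None:
        q = tuple(float(v) for v in self.q)
        lam = tuple(float(v) for v in self.lam)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "lam", lam)
        if len(q) != len(lam) or len(q) == 0:
            raise ValueError("q and lam must be non-empty and of equal length")
        if any(w <= 0 for w in q):
            raise ValueError("all weights must be positive")
        if abs(sum(q) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {sum(q)!r})")
        if any(l < 0 for l in lam):
            raise ValueError("rates must be non-negative")
        if any(b <= a for a, b in zip(lam, lam[1:])):
            raise ValueError("rates must be strictly increasing")
        if not self.window_years > 0:
            raise ValueError("window_years must be positive")

    @classmethod
    def from_components(
        cls,
        q: Sequence[float],
        lam: Sequence[float],
        window_years: float = 1.0,
        normalise: bool = False,
    ) -> "MixtureDistribution":
        """Build a mixture from unsorted components.

        Sorts by rate, merges exact duplicates (weights summed), drops
        zero-weight components and optionally renormalises the weights.
        """
        q = np.asarray(q, dtype=float)
        lam = np.asarray(lam, dtype=float)
        if q.shape != lam.shape:
            raise ValueError("q and lam must have equal length")
        keep = q > 0
        q, lam = q[keep], lam[keep]
        if q.size == 0:
            raise ValueError("no components with positive weight")
        order = np.argsort(lam)
        q, lam = q[order], lam[order]
        merged_q, merged_lam = [q[0]], [lam[0]]
        for w, l in zip(q[1:], lam[1:]):
            if l == merged_lam[-1]:
                merged_q[-1] += w
            else:
                merged_q.append(w)
                merged_lam.append(l)
        q = np.asarray(merged_q)
        if normalise:
            q = q / q.sum()
        return cls(tuple(q), tuple(merged_lam), window_years=window_years)

    @property
    def k(self) -> int:
        """Number of mixture groups."""
        return len(self.q)

    @property
    def mean_rate(self) -> float:
        """Mean rate per unit per window, ``sum(q_j * lam_j)``."""
        return float(np.dot(self.q, self.lam))

    def scaled(self, factor: float) -> "MixtureDistribution":
        """Rescale all rates by ``factor`` (e.g. window-to-year conversion).

        ``window_years`` is scaled by the same factor so the per-year
        interpretation is preserved.
        """
        if not factor > 0:
            raise ValueError("factor must be positive")
        return MixtureDistribution(
            self.q,
            tuple(l * factor for l in self.lam),
            window_years=self.window_years * factor,
        )

    def expected_zero_share(self) -> float:
        """Expected fraction of zero-count units, ``sum(q_j * exp(-lam_j))``."""
        return float(np.dot(self.q, np.exp(-np.asarray(self.lam))))


@dataclass
class FitResult:
    """Outcome of a non-parametric maximum-likelihood mixture fit.

    ``em_loglik_traces`` holds one log-likelihood trace per EM run
    (runs restart after support insertion or collapsing); each trace
    is non-decreasing.
    """

    mixture: MixtureDistribution
    loglik: float
    n_iter_vem: int
    n_iter_em: int
    max_gradient: float
    converged: bool
    em_loglik_traces: list = field(default_factory=list)


@dataclass
class GofReport:
    """Parametric-bootstrap likelihood-ratio test report."""

    statistic: float
    p_value: float
    k_null: int
    k_alt: int
    n_boot: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class LorenzCurve:
    """Piecewise-linear Lorenz curve.

    ``points`` is an (m, 2) array of (cumulative unit share, cumulative
    rate share) vertices, starting at (0, 0) and ending at (1, 1).
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("points must be an (m, 2) array with m >= 2")
        if not (np.allclose(pts[0], [0, 0]) and np.allclose(pts[-1], [1, 1])):
            raise ValueError("curve must run from (0, 0) to (1, 1)")
        if np.any(np.diff(pts[:, 0]) < -1e-12) or np.any(np.diff(pts[:, 1]) < -1e-12):
            raise ValueError("curve must be non-decreasing in both coordinates")

    @property
    def u(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def v(self) -> np.ndarray:
        return self.points[:, 1]

    def area_below(self) -> float:
        """Area under the curve, exact trapezoids on the vertex set."""
        return float(np.trapezoid(self.v, self.u))

    def area_between_diagonal(self) -> float:
        """Area between the equality diagonal and the curve."""
        return 0.5 - self.area_below()


@dataclass
class ConcentrationReport:
    """Summary of event-rate concentration for one dataset."""

    recc: float
    mean_rate: float
    lorenz: LorenzCurve
    naive_gini: Optional[float] = None
    ci: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.recc <= 1.0 and math.isfinite(self.recc)):
            raise ValueError("recc must lie in [0, 1]")
        if self.naive_gini is not None and not 0.0 <= self.naive_gini <= 1.0:
            raise ValueError("naive_gini must lie in [0, 1]")


@dataclass
class ReccCI:
    """Monte Carlo percentile confidence interval for an observed RECC."""

    observed: float
    lo: float
    hi: float
    level: float
    reps: int
    effective_reps: int
    seed: Optional[int]
    replicate_values: np.ndarray
    refit: bool = True

    def __post_init__(self) -> None:
        self.replicate_values = np.asarray(self.replicate_values, dtype=float)
        if self.lo > self.hi:
            raise ValueError("lo must not exceed hi")
        if self.replicate_values.size != self.effective_reps:
            raise ValueError("replicate_values length must equal effective_reps")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi
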