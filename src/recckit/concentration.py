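"""Concentration metrics: RECC, Lorenz curves, naive Gini, exposure ratios.

The Rare Event Concentration Coefficient (RECC) is the Gini coefficient
of the fitted distribution of per-unit event rates,

    RECC = sum_i sum_j q_i q_j |lam_i - lam_j| / (2 sum_i q_i lam_i),

as opposed to the "naive" Gini computed directly on raw counts, which
is inflated by the abundance of zeros in rare-event data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import ConcentrationReport, CountVector, LorenzCurve, MixtureDistribution

__all__ = [
    "recc",
    "lorenz",
    "naive_gini",
    "zero_floor",
    "concentration_report",
    "ExposureTable",
    "exposure_risk",
]


def recc(mix: MixtureDistribution) -> float:
    """Rare Event Concentration Coefficient of a fitted mixture.

    Returns 0 (with a warning) when the mean rate is zero: all-zero
    rates are perfectly homogeneous.
    """
    q = np.asarray(mix.q)
    lam = np.asarray(mix.lam)
    mean = float(q @ lam)
    if mean == 0.0:
        warnings.warn("mean rate is zero; RECC defined as 0", stacklevel=2)
        return 0.0
    diff = np.abs(lam[:, None] - lam[None, :])
    return float(q @ diff @ q / (2.0 * mean))


def lorenz(mix: MixtureDistribution) -> LorenzCurve:
    """Lorenz curve of the rate distribution.

    With rates ascending, vertex ``m`` is
    ``(sum_{j<=m} q_j, sum_{j<=m} q_j lam_j / mean)``.  Twice the area
    between the diagonal and the curve equals :func:`recc`.
    """
    q = np.asarray(mix.q)
    lam = np.asarray(mix.lam)
    mean = float(q @ lam)
    u = np.concatenate([[0.0], np.cumsum(q)])
    u[-1] = 1.0  # guard cumulative rounding
    if mean == 0.0:
        warnings.warn("mean rate is zero; Lorenz curve degenerates to the diagonal",
                      stacklevel=2)
        v = u.copy()
    else:
        v = np.concatenate([[0.0], np.cumsum(q * lam) / mean])
        v[-1] = 1.0
    return LorenzCurve(np.column_stack([u, v]))


def naive_gini(counts: Union[CountVector, Sequence[int]]) -> float:
    """Gini coefficient of the raw count vector.

    ``sum_i sum_j |H_i - H_j| / (2 N sum H)``; provided for comparison
    with the RECC, not as the headline metric.  Computed by the
    O(N log N) sorted-rank identity.
    """
    h = counts.counts if isinstance(counts, CountVector) else np.asarray(counts)
    if h.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(h < 0):
        raise ValueError("counts must be non-negative")
    total = h.sum()
    if total == 0:
        warnings.warn("all counts are zero; Gini defined as 0", stacklevel=2)
        return 0.0
    n = h.size
    x = np.sort(h).astype(float)
    ranks = np.arange(1, n + 1)
    return float((2.0 * ranks - n - 1.0) @ x / (n * total))


def zero_floor(n_units: int, n_events: int) -> float:
    """Minimal achievable share of zero-count units.

    ``max(0, (n_units - n_events) / n_units)`` — attained when every
    event occupies a distinct unit.
    """
    if n_units < 1:
        raise ValueError("n_units must be at least 1")
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    return max(0.0, (n_units - n_events) / n_units)


def concentration_report(
    mix: MixtureDistribution,
    counts: Optional[CountVector] = None,
    ci: Optional[tuple] = None,
) -> ConcentrationReport:
    """Bundle RECC, Lorenz curve and (optionally) the naive count Gini."""
    return ConcentrationReport(
        recc=recc(mix),
        mean_rate=mix.mean_rate,
        lorenz=lorenz(mix),
        naive_gini=None if counts is None else naive_gini(counts),
        ci=ci,
    )


_EXPOSURE_COLUMNS = ("road", "length_km", "flow", "accidents", "fatalities")


@dataclass
class ExposureTable:
    """Per-road exposure data: length, flow, accident and fatality counts.

    ``flow`` is in millions of vehicle-kilometres per year.  Wraps a
    DataFrame with columns ``road, length_km, flow, accidents,
    fatalities`` (extra columns pass through untouched).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _EXPOSURE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"exposure table missing columns: {missing}")
        num = self.data[list(_EXPOSURE_COLUMNS[1:])]
        if (num < 0).any().any():
            raise ValueError("exposure quantities must be non-negative")
        self.data = self.data.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "ExposureTable":
        return cls(pd.DataFrame.from_records(records, columns=_EXPOSURE_COLUMNS))

    def _row(self, road: str) -> pd.Series:
        match = self.data[self.data["road"] == road]
        if match.empty:
            raise KeyError(f"unknown road: {road!r}")
        return match.iloc[0]

    def risk(self, road: str) -> float:
        """Accidents per unit flow."""
        row = self._row(road)
        if row["flow"] <= 0:
            raise ValueError(f"road {road!r} has zero flow")
        return float(row["accidents"] / row["flow"])

    def lethality(self, road: str) -> float:
        """Fatalities per unit flow."""
        row = self._row(road)
        if row["flow"] <= 0:
            raise ValueError(f"road {road!r} has zero flow")
        return float(row["fatalities"] / row["flow"])

    def risk_ratio(self, road_a: str, road_b: str) -> float:
        return self.risk(road_a) / self.risk(road_b)

    def lethality_ratio(self, road_a: str, road_b: str) -> float:
        return self.lethality(road_a) / self.lethality(road_b)


def exposure_risk(table: ExposureTable) -> pd.DataFrame:
    """Per-road risk and lethality rates.

    Returns a DataFrame with ``road, risk, lethality`` columns; raises
    on any zero flow.
    """
    df = table.data
    if (df["flow"] <= 0).any():
        bad = df.loc[df["flow"] <= 0, "road"].tolist()
        raise ValueError(f"zero flow for roads: {bad}")
    return pd.DataFrame(
        {
            "road": df["road"],
            "risk": df["accidents"] / df["flow"],
            "lethality": df["fatalities"] / df["flow"],
        }
    )
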