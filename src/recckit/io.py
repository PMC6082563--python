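"""File readers and writers: CSV events and counts, JSON models and
reports, GeoJSON hexagon export, and human-readable table rendering.

CSV handling is strict RFC-4180 via pandas; no dialect sniffing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .concentration import ExposureTable
from .core import (
    ConcentrationReport,
    CountVector,
    FitResult,
    LorenzCurve,
    MixtureDistribution,
    PointEvent,
    ReccCI,
)
from .spatial.hexgrid import HexGrid, hex_polygon

logger = logging.getLogger(__name__)

__all__ = [
    "SEVERITY_LABELS",
    "ReadResult",
    "read_point_events",
    "read_linear_events",
    "read_counts_csv",
    "write_counts_csv",
    "read_exposure_csv",
    "mixture_to_json",
    "mixture_from_json",
    "write_mixture_json",
    "read_mixture_json",
    "write_mixture_csv",
    "read_mixture_csv",
    "write_lorenz_csv",
    "write_report_json",
    "render_mixture_table",
    "hexgrid_to_geojson",
]

#: The fixed severity taxonomy; unknown labels pass through but are
#: excluded by any filter.
SEVERITY_LABELS = ("fatal", "serious", "slight")


@dataclass
class ReadResult:
    """Parsed rows plus a counter of rows skipped for parse failures."""

    events: list = field(default_factory=list)
    n_skipped: int = 0


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, skipinitialspace=True)


def read_point_events(
    path,
    severity_filter: Optional[Sequence[str]] = None,
    strict: bool = False,
) -> ReadResult:
    """Read planar events from a CSV with ``x,y[,severity][,date]`` columns.

    Rows whose coordinates fail numeric parsing are skipped and counted
    (error in strict mode).  ``severity_filter`` keeps only rows whose
    (case-insensitive) label is in the given set.
    """
    df = _read_csv(path)
    missing = [c for c in ("x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing}; found {list(df.columns)}")
    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    ok = x.notna() & y.notna() & np.isfinite(x.fillna(np.nan)) & np.isfinite(y.fillna(np.nan))
    n_skipped = int((~ok).sum())
    if n_skipped:
        if strict:
            raise ValueError(f"{n_skipped} row(s) with unparseable coordinates")
        logger.warning("skipped %d row(s) with unparseable coordinates", n_skipped)
    severity = df["severity"].astype(str).str.strip().str.lower() if "severity" in df else None
    dates = df["date"].astype(str) if "date" in df else None
    if severity_filter is not None:
        wanted = {s.lower() for s in severity_filter}
        if severity is None:
            raise ValueError("severity filter requested but no severity column present")
        ok &= severity.isin(wanted)
    events = [
        PointEvent(
            float(x[i]),
            float(y[i]),
            severity=None if severity is None else severity[i],
            t=None if dates is None else dates[i],
        )
        for i in df.index[ok]
    ]
    return ReadResult(events=events, n_skipped=n_skipped)


def read_linear_events(path, strict: bool = False) -> ReadResult:
    """Read kilometre-post positions from a CSV with a ``km`` column."""
    df = _read_csv(path)
    if "km" not in df.columns:
        raise ValueError(f"missing mandatory column 'km'; found {list(df.columns)}")
    km = pd.to_numeric(df["km"], errors="coerce")
    ok = km.notna()
    n_skipped = int((~ok).sum())
    if n_skipped:
        if strict:
            raise ValueError(f"{n_skipped} row(s) with unparseable km positions")
        logger.warning("skipped %d row(s) with unparseable km positions", n_skipped)
    if strict and (km[ok] < 0).any():
        raise ValueError("negative km position in strict mode")
    if df.empty:
        logger.warning("empty input file: %s", path)
    return ReadResult(events=[float(v) for v in km[ok]], n_skipped=n_skipped)


def read_counts_csv(path, window_years: float = 1.0) -> CountVector:
    """Read a per-unit count vector from a ``unit_id,count`` CSV."""
    df = _read_csv(path)
    if "count" not in df.columns:
        raise ValueError(f"missing mandatory column 'count'; found {list(df.columns)}")
    unit_ids = df["unit_id"].tolist() if "unit_id" in df.columns else None
    return CountVector(df["count"].to_numpy(), unit_ids=unit_ids, window_years=window_years)


def write_counts_csv(counts: CountVector, path) -> None:
    pd.DataFrame({"unit_id": [str(u) for u in counts.unit_ids],
                  "count": counts.counts}).to_csv(path, index=False)


def read_exposure_csv(path) -> ExposureTable:
    """Read a per-road exposure table (road,length_km,flow,accidents,fatalities)."""
    return ExposureTable(_read_csv(path))


def mixture_to_json(mix: MixtureDistribution) -> dict:
    return {
        "k": mix.k,
        "q": list(mix.q),
        "lambda": list(mix.lam),
        "window_years": mix.window_years,
    }


def mixture_from_json(obj: dict) -> MixtureDistribution:
    return MixtureDistribution(
        tuple(obj["q"]), tuple(obj["lambda"]), window_years=obj.get("window_years", 1.0)
    )


def write_mixture_json(mix: MixtureDistribution, path) -> None:
    with open(path, "w") as fh:
        json.dump(mixture_to_json(mix), fh, indent=2)
        fh.write("\n")


def read_mixture_json(path) -> MixtureDistribution:
    with open(path) as fh:
        return mixture_from_json(json.load(fh))


def write_mixture_csv(mix: MixtureDistribution, path) -> None:
    """Mixture as a ``group,size,rate`` CSV (sizes as percentages)."""
    pd.DataFrame(
        {
            "group": range(1, mix.k + 1),
            "size": [100.0 * w for w in mix.q],
            "rate": mix.lam,
        }
    ).to_csv(path, index=False)


def read_mixture_csv(path, window_years: float = 1.0) -> MixtureDistribution:
    df = _read_csv(path)
    missing = [c for c in ("size", "rate") if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing}")
    return MixtureDistribution.from_components(
        df["size"].to_numpy() / 100.0,
        df["rate"].to_numpy(),
        window_years=window_years,
        normalise=True,
    )


def write_lorenz_csv(curve: LorenzCurve, path) -> None:
    """Lorenz curve as a two-column (u, v) CSV, endpoints included."""
    pd.DataFrame({"u": curve.u, "v": curve.v}).to_csv(path, index=False)


def _report_to_obj(report) -> dict:
    if isinstance(report, ConcentrationReport):
        return {
            "type": "concentration_report",
            "recc": report.recc,
            "naive_gini": report.naive_gini,
            "mean_rate": report.mean_rate,
            "lorenz": [list(p) for p in report.lorenz.points],
            "ci": list(report.ci) if report.ci is not None else None,
        }
    if isinstance(report, FitResult):
        return {
            "type": "fit_result",
            "mixture": mixture_to_json(report.mixture),
            "loglik": report.loglik,
            "n_iter_vem": report.n_iter_vem,
            "n_iter_em": report.n_iter_em,
            "max_gradient": report.max_gradient,
            "converged": report.converged,
        }
    if isinstance(report, ReccCI):
        return {
            "type": "recc_ci",
            "observed": report.observed,
            "lo": report.lo,
            "hi": report.hi,
            "level": report.level,
            "reps": report.reps,
            "effective_reps": report.effective_reps,
            "seed": report.seed,
            "refit": report.refit,
            "replicate_values": report.replicate_values.tolist(),
        }
    raise TypeError(f"unsupported report type: {type(report).__name__}")


def write_report_json(report, path) -> None:
    """Serialise a report object (JSON; round-trippable for mixtures)."""
    with open(path, "w") as fh:
        json.dump(_report_to_obj(report), fh, indent=2)
        fh.write("\n")


def render_mixture_table(mix: MixtureDistribution) -> str:
    """Aligned text table: one row per group with size (%) and rate.

    Weights are rendered as percentages to one decimal; rates to three
    decimals.  Machine-readable output keeps full precision.
    """
    lines = [f"{'group':>5}  {'size %':>7}  {'rate':>8}"]
    for j, (w, l) in enumerate(zip(mix.q, mix.lam), start=1):
        lines.append(f"{j:>5}  {100 * w:>7.1f}  {l:>8.3f}")
    return "\n".join(lines)


def hexgrid_to_geojson(grid: HexGrid, counts: Optional[CountVector] = None) -> dict:
    """GeoJSON FeatureCollection of hexagon polygons with count properties."""
    count_by_axial = {}
    if counts is not None:
        count_by_axial = dict(zip(counts.unit_ids, counts.counts.tolist()))
    features = []
    for axial in grid.axials:
        poly = hex_polygon(grid, axial)
        props = {"aq": axial[0], "ar": axial[1]}
        if counts is not None:
            props["count"] = int(count_by_axial.get(axial, 0))
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [list(map(list, poly.exterior.coords))],
                },
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}
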