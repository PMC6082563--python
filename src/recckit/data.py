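"""Bundled reference inputs from the published road-accident analyses.

Small printed tables used by the examples, the built-in synthetic
scenarios and the acceptance report: severity frequencies for Greater
London collisions (2005-2014), exposure figures for the nine motorways
radiating from Mexico City (2015-2016), and fitted rate distributions
reported for those datasets.
"""

from __future__ import annotations

from .concentration import ExposureTable
from .core import MixtureDistribution

__all__ = [
    "LONDON_SEVERITY_COUNTS",
    "MOTORWAY_EXPOSURE",
    "URBAN_SEVERE_MIXTURE",
    "PACHUCA_3GROUP_MIXTURE",
    "PUEBLA_UNIFORM_RATE",
    "PACHUCA_TOP_RATE",
]

#: Collision counts by severity category, Greater London 2005-2014.
LONDON_SEVERITY_COUNTS = {"fatal": 1_670, "serious": 27_788, "slight": 213_324}

#: Length (km), flow (million vehicle-km/year), accident and fatality
#: counts for the nine motorways with origin in Mexico City, 2015-2016.
MOTORWAY_EXPOSURE = ExposureTable.from_records(
    [
        ("cuernavaca_federal", 60.5, 467.9, 105, 22),
        ("cuernavaca_toll", 70.7, 1204.7, 106, 23),
        ("toluca_federal", 55.0, 764.5, 117, 20),
        ("toluca_toll", 55.0, 1589.4, 46, 15),
        ("pachuca_federal", 62.5, 1761.3, 162, 29),
        ("pachuca_toll", 62.5, 1083.3, 62, 20),
        ("puebla_federal", 121.0, 2736.3, 49, 13),
        ("puebla_toll", 121.0, 2725.7, 162, 46),
        ("queretaro_toll", 164.0, 1548.8, 293, 64),
    ]
)

#: 12-group rate distribution fitted to serious+fatal collisions on the
#: 29,600-tile London grid (rates per tile per 10-year window).
URBAN_SEVERE_MIXTURE = MixtureDistribution(
    q=(0.642, 0.227, 0.021, 0.019, 0.017, 0.015, 0.013, 0.012, 0.010, 0.010, 0.010, 0.004),
    lam=(0.000, 0.488, 0.823, 1.159, 1.517, 1.906, 2.337, 2.839, 3.466, 4.359, 5.860, 10.950),
    window_years=10.0,
)

#: 3-group rate distribution for the Pachuca federal road (per 500-m
#: segment per 2-year window).  The published sizes (17%, 74%, 8.2%)
#: sum to 99.2% as printed; they are renormalised here.
PACHUCA_3GROUP_MIXTURE = MixtureDistribution.from_components(
    q=(0.17, 0.74, 0.082),
    lam=(0.0, 1.36, 3.4),
    window_years=2.0,
    normalise=True,
)

#: Single fitted rate on the Puebla federal road, per 500-m segment per
#: 2-year window (near-uniform accident pattern).
PUEBLA_UNIFORM_RATE = 0.1978

#: Highest fitted group rate on the Pachuca federal road, per 500-m
#: segment per 2-year window.
PACHUCA_TOP_RATE = 3.44
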