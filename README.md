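# recckit

Rare-event concentration analysis for spatial and linear event data
(road accidents, crime, industrial incidents, ...).

Low-frequency events make the usual concentration measures misleading:
a Gini coefficient computed directly on per-unit counts is inflated by
the abundance of zero-count units. `recckit` instead models per-unit
counts as a finite Poisson mixture estimated by non-parametric maximum
likelihood and summarises concentration with the **Rare Event
Concentration Coefficient (RECC)** — the Gini coefficient of the fitted
distribution of *rates* rather than of raw counts.

The pipeline:

1. **Discretise** — hex-bin planar events (`build_hex_grid`,
   `assign_points_to_hexes`) or bin kilometre-post events into
   fixed-length road segments (`segment_road`); test point patterns
   against complete spatial randomness (`nearest_neighbour_csr_test`,
   Clark–Evans with Donnelly edge correction and optional Monte Carlo
   envelope).
2. **Fit** — `fit_npmle` estimates the mixing distribution of rates
   (vertex-exchange initialisation, EM refinement, constrained-Newton
   weight steps, support-point collapsing) with an optimality
   certificate `sup d(λ) ≤ 1 + tol` on the gradient function;
   `bootstrap_lrt` provides the model-acceptance test and
   `fit_parsimonious` combines the two.
3. **Score** — `recc`, `lorenz`, `naive_gini`, `zero_floor`, per-road
   `exposure_risk` ratios, and `recc_confidence_interval` (Monte Carlo
   percentile interval treating the fitted distribution as truth).
4. **Simulate** — `synthetic` ships named scenarios
   (`london_table4`, `puebla_uniform`, `pachuca_3group`, `csr_null`)
   so the whole pipeline is testable without external data.

Coordinates are assumed already projected to planar metres; the package
performs no CRS transformations.

## Command line

```sh
recckit simulate --scenario pachuca_3group --seed 1 --out counts.csv
recckit fit --in counts.csv --out mixture.json
recckit recc --mixture mixture.json --counts counts.csv --lorenz-out lorenz.csv
recckit ci --mixture mixture.json --n-units 125 --reps 199 --seed 1
recckit segment --in km_events.csv --road-length 121 --out counts.csv
recckit tessellate --in xy_events.csv --side 40 --out counts.csv --geojson tiles.geojson
recckit csr-test --in xy_events.csv --n-sims 199 --seed 1
recckit exposure --in exposure.csv --compare cuernavaca_federal puebla_federal
```

Input formats: CSV with `x,y[,severity][,date]` columns (planar events,
metres), `km` column (linear events), `unit_id,count` (count vectors),
`road,length_km,flow,accidents,fatalities` (exposure tables). Models
are serialised as JSON `{k, q[], lambda[], window_years}`.

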