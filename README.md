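# gistar

Local Getis-Ord Gi* segregation statistics for census tracts.

Given tract polygons and a per-tract population table, `gistar`:

1. builds **queen or rook contiguity** weights from the polygons
   (self-included and row-standardized, so each focal tract and its
   neighbors share equal weights summing to one);
2. assigns every tract a **larger areal unit** — the CBSA-like polygon
   containing its representative interior point, or, failing that, the
   county given by the first five digits of its FIPS identifier;
3. computes, per population group and per unit, the standardized
   **Gi\* Z-score** — how much the group proportion in the focal tract and
   its neighbors deviates from the unit mean;
4. writes a fixed CSV schema (`FIPS_ID`, then `{group}_Gstat` and
   `{group}_n_neigh` per group; nine columns with the four default
   groups), using reserved negative **indicator codes** where the
   statistic is undefined:

| reason | code |
|---|---|
| only one tract in the unit | −99 |
| zero population in the focal tract | −100 |
| no target population in the unit | −199 |
| tract adjacent to every other tract in the unit | −299 |
| all tracts in the unit are islands | −399 |

Geometry is read from GeoJSON or ESRI Shapefile (a small built-in polygon
codec; no GIS stack needed beyond shapely). A synthetic-fixture module
(`gistar.synthetic`) generates lattice "cities", seeded population
scenarios and minimal fixtures for each indicator code, so everything is
testable offline.

## CLI

```sh
gistar compute \
  --geometry tracts.geojson \
  --population pop.csv \
  [--cbsa cbsa.geojson] \
  --groups nhWhite,nhBlack,nhAsian,Hispanic \
  --contiguity queen \
  [--snap-tolerance 0.0] [--pad-fips] \
  -o out.csv -v
```

The population CSV needs a `FIPS_ID` column (10- or 11-digit identifiers),
one integer count column per group, and a `total` column. All flags can
also be given in a `key = value` config file via `--config` (explicit
flags win). `--pad-fips` keeps the leading zero in output identifiers;
by default they are written in the zero-stripped numeric style.

The same pipeline is available programmatically via
`gistar.run_pipeline(geometry, population, cbsa_geometry, config)`.

## Notes

- Contiguity is computed within each larger unit; a tract's geometric
  neighbors in another unit never contribute.
- Zero-population tracts are coded −100 and removed from the unit's mean,
  standard deviation and neighbors' weight rows (rows re-standardized).
- Constant proportions within a unit (zero variance) yield an empty cell
  plus a warning — there is no reserved code for that case.
- Rook adjacency requires a shared boundary longer than `--snap-tolerance`
  (default 0, i.e. any positive-length shared segment); queen requires any
  shared boundary point. Software packages differ in this threshold, so it
  is exposed as a parameter.
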