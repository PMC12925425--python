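"""End-to-end orchestration: units -> contiguity -> Gi* -> coded table.

Each larger areal unit is processed independently: contiguity is built on
the unit's members only, proportions and the statistic are computed within
the unit, and tracts for which the statistic is undefined receive a
reserved negative indicator code instead of a Z-score.  Per-unit result
rows are concatenated and sorted by FIPS.
"""

from __future__ import annotations

import logging
import math
import time
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .areal import ArealUnitPartition, assign_larger_unit
from .contiguity import NeighborGraph, build_neighbor_graph, row_standardize_with_self
from .errors import IdMismatchError, ZeroVarianceError
from .getisord import compute_group_proportions, gi_star_unit
from .groups import DEFAULT_GROUPS
from .io_formats import read_population_table, read_polygon_layer, read_tract_geometry, write_results_csv

logger = logging.getLogger(__name__)

# Indicator codes written in place of a Z-score when it is undefined.
CODE_SINGLE_TRACT = -99        # only one tract in the unit
CODE_ZERO_POPULATION = -100    # zero total population in the focal tract
CODE_NO_TARGET_POPULATION = -199  # group absent from the whole unit
CODE_FULLY_CONNECTED = -299    # focal tract adjacent to every other tract
CODE_ALL_ISLANDS = -399        # no tract in the unit has any neighbor

INDICATOR_CODES = (
    CODE_SINGLE_TRACT,
    CODE_ZERO_POPULATION,
    CODE_NO_TARGET_POPULATION,
    CODE_FULLY_CONNECTED,
    CODE_ALL_ISLANDS,
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    groups: Sequence[str] = DEFAULT_GROUPS
    contiguity: str = "queen"
    snap_tolerance: float = 0.0
    output_path: Optional[str] = None
    pad_fips: bool = False

    def __post_init__(self):
        if not self.groups:
            raise ValueError("at least one group is required")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group names must be unique")
        if self.contiguity not in ("queen", "rook"):
            raise ValueError(f"unknown contiguity mode {self.contiguity!r}")


def classify_degenerate(
    members: Sequence[str],
    graph: NeighborGraph,
    totals: Mapping[str, int],
    group_counts: Mapping[str, int],
    focal: str,
) -> Optional[int]:
    """Return the indicator code for ``focal``, or None if a Z is computable.

    Codes are checked in fixed precedence order (unit-level before
    tract-level connectivity): single-tract unit, zero focal population,
    no target population in the unit, focal connected to every other
    tract, all tracts islands.
    """
    n = len(members)
    if n == 1:
        return CODE_SINGLE_TRACT
    if totals[focal] == 0:
        return CODE_ZERO_POPULATION
    if sum(group_counts[t] for t in members) == 0:
        return CODE_NO_TARGET_POPULATION
    if len(graph.neighbors[focal]) == n - 1:
        return CODE_FULLY_CONNECTED
    if all(len(graph.neighbors[t]) == 0 for t in members):
        return CODE_ALL_ISLANDS
    return None


def _unit_results(
    unit_id: str,
    members: Sequence[str],
    geometry: Mapping,
    population: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Compute all cells for one unit; returns {tract: {column: value}}."""
    members = sorted(members)
    graph = build_neighbor_graph(
        {t: geometry[t] for t in members},
        mode=config.contiguity,
        snap_tolerance=config.snap_tolerance,
    )
    n_neigh = graph.neighbor_counts()
    totals = {t: int(population.at[t, "total"]) for t in members}

    # zero-population tracts leave the unit entirely: excluded from x-bar/s
    # and dropped from neighbors' weight rows (rows re-standardized).
    populated = [t for t in members if totals[t] > 0]
    weights = row_standardize_with_self(graph.restricted_to(populated))

    rows: dict = {t: {} for t in members}
    for g in config.groups:
        counts = {t: int(population.at[t, g]) for t in members}
        codes = {
            t: classify_degenerate(members, graph, totals, counts, t) for t in members
        }
        uncoded = [t for t in members if codes[t] is None]

        z: dict = {}
        if uncoded:
            xv, _flagged = compute_group_proportions(
                {t: counts[t] for t in populated},
                {t: totals[t] for t in populated},
                unit_id=unit_id,
            )
            if xv.n < 2:
                warnings.warn(
                    f"unit {unit_id!r}: fewer than 2 populated tracts; "
                    f"group {g!r} left missing",
                    stacklevel=2,
                )
            else:
                try:
                    z = gi_star_unit(xv, weights, strict=False)
                except ZeroVarianceError:
                    warnings.warn(
                        f"unit {unit_id!r}: constant proportions for group "
                        f"{g!r}; values left missing",
                        stacklevel=2,
                    )

        for t in members:
            if codes[t] is not None:
                cell = codes[t]
            elif (
                t in weights
                and len(populated) > 1
                and weights[t].n_neigh == len(populated) - 1
            ):
                # denominator degenerated only after zero-population removal
                cell = CODE_FULLY_CONNECTED
            elif t in z:
                cell = z[t]
            else:
                cell = math.nan
            rows[t][f"{g}_Gstat"] = cell
            rows[t][f"{g}_n_neigh"] = n_neigh[t]
    return rows


def run_pipeline(
    geometry: Mapping,
    population: pd.DataFrame,
    cbsa_geometry: Optional[Mapping] = None,
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Run the full computation on in-memory inputs.

    Parameters
    ----------
    geometry : mapping of canonical FIPS -> shapely polygon
    population : DataFrame indexed by canonical FIPS
        Must carry one column per configured group plus ``"total"``.
    cbsa_geometry : mapping of unit id -> polygon, optional
        Non-overlapping larger-unit polygons; tracts outside them (or all
        tracts, when absent) fall back to their county.
    config : RunConfig

    Returns
    -------
    pandas.DataFrame
        One row per input tract, indexed by canonical FIPS (sorted), with
        ``{group}_Gstat`` (float Z, int indicator code, or NaN) and
        ``{group}_n_neigh`` columns in group order.

    Raises
    ------
    IdMismatchError
        If geometry and population identifier sets differ.
    """
    t0 = time.perf_counter()
    geo_ids = set(geometry)
    pop_ids = set(population.index)
    if geo_ids != pop_ids:
        raise IdMismatchError(geo_ids - pop_ids, pop_ids - geo_ids)

    partition = assign_larger_unit(geometry, cbsa_geometry)
    kinds = Counter(kind for _, kind in partition.assignment.values())
    logger.info(
        "%d tracts in %d units (%d cbsa-assigned, %d county-fallback)",
        len(geometry), len(partition.units), kinds.get("cbsa", 0), kinds.get("county", 0),
    )

    all_rows: dict = {}
    for unit_id in sorted(partition.units):
        all_rows.update(
            _unit_results(unit_id, partition.units[unit_id], geometry, population, config)
        )

    index = pd.Index(sorted(all_rows), name="FIPS_ID")
    columns = []
    for g in config.groups:
        columns += [f"{g}_Gstat", f"{g}_n_neigh"]
    table = pd.DataFrame(
        [[all_rows[t][c] for c in columns] for t in index],
        index=index,
        columns=columns,
        dtype=object,  # keep indicator codes as ints next to float Z-scores
    )
    for g in config.groups:
        table[f"{g}_n_neigh"] = table[f"{g}_n_neigh"].astype("int64")

    tally = Counter(
        int(v)
        for g in config.groups
        for v in table[f"{g}_Gstat"]
        if isinstance(v, int) and v in INDICATOR_CODES
    )
    logger.info(
        "indicator-code tally: %s; elapsed %.2fs",
        dict(sorted(tally.items())) or "none", time.perf_counter() - t0,
    )

    if config.output_path:
        write_results_csv(table, config.output_path, pad_fips=config.pad_fips)
        logger.info("wrote %s", config.output_path)
    return table


def run_pipeline_files(
    geometry_path,
    population_path,
    cbsa_path=None,
    config: RunConfig = RunConfig(),
    id_field: Optional[str] = None,
    cbsa_id_field: Optional[str] = None,
) -> pd.DataFrame:
    """File-based front end to :func:`run_pipeline` (used by the CLI)."""
    geometry = read_tract_geometry(geometry_path, id_field=id_field)
    population = read_population_table(population_path, groups=config.groups)
    cbsa = read_polygon_layer(cbsa_path, id_field=cbsa_id_field) if cbsa_path else None
    return run_pipeline(geometry, population, cbsa_geometry=cbsa, config=config)
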