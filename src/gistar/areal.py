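"""Assignment of tracts to their larger areal unit (CBSA-like or county).

A tract belongs to the CBSA-like polygon that contains its representative
interior point; tracts outside every such polygon fall back to the county
implied by the first five digits of their FIPS identifier.  The fallback is
purely lexical and involves no geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from shapely.strtree import STRtree

from .errors import OverlappingUnitsError
from .io_formats import parse_fips

CBSA = "cbsa"
COUNTY = "county"


@dataclass(frozen=True)
class ArealUnitPartition:
    """Partition of the tract set into larger areal units.

    ``assignment`` maps each tract id to ``(unit_id, unit_kind)`` with
    ``unit_kind`` in {"cbsa", "county"}; ``units`` is its inverse.
    """

    assignment: Mapping[str, tuple]
    units: Mapping[str, frozenset]

    def __post_init__(self):
        n = sum(len(m) for m in self.units.values())
        if n != len(self.assignment):
            raise ValueError("units do not partition the tract set")


def assign_larger_unit(
    tracts: Mapping[str, object],
    cbsa_polygons: Optional[Mapping[str, object]] = None,
) -> ArealUnitPartition:
    """Assign every tract a larger areal unit.

    Parameters
    ----------
    tracts : mapping of canonical FIPS id -> shapely polygon
    cbsa_polygons : mapping of unit id -> shapely polygon, optional
        Non-overlapping CBSA-like polygons.  When absent, every tract is
        assigned its county.

    Returns
    -------
    ArealUnitPartition

    Raises
    ------
    FipsFormatError
        If a tract id does not parse as a FIPS code.
    OverlappingUnitsError
        If a tract's representative point lies inside two or more CBSA
        polygons (both unit ids are reported).
    """
    tree = None
    unit_ids: list = []
    if cbsa_polygons:
        unit_ids = list(cbsa_polygons)
        tree = STRtree(np.array([cbsa_polygons[u] for u in unit_ids], dtype=object))

    assignment = {}
    for tid, geom in tracts.items():
        fips = parse_fips(tid)
        unit = (fips.state + fips.county, COUNTY)
        if tree is not None:
            point = geom.representative_point()
            hits = sorted(unit_ids[k] for k in tree.query(point, predicate="within"))
            if len(hits) > 1:
                raise OverlappingUnitsError(tid, hits)
            if hits:
                unit = (hits[0], CBSA)
        assignment[tid] = unit

    units: dict = {}
    for tid, (unit_id, _) in assignment.items():
        units.setdefault(unit_id, set()).add(tid)
    return ArealUnitPartition(
        assignment=assignment,
        units={u: frozenset(m) for u, m in units.items()},
    )
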