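"""Exception hierarchy shared across the package."""

from __future__ import annotations


class GistarError(Exception):
    """Base class for all errors raised by this package."""


class InvalidGeometryError(GistarError):
    """A polygon is missing, empty, non-polygonal or self-intersecting."""

    def __init__(self, uid: str, reason: str = "invalid geometry"):
        self.uid = uid
        super().__init__(f"{reason}: {uid!r}")


class DuplicateIdError(GistarError):
    """The same identifier appears more than once in a layer."""

    def __init__(self, uid: str):
        self.uid = uid
        super().__init__(f"duplicate identifier: {uid!r}")


class FipsFormatError(GistarError):
    """An identifier does not parse as a 10/11-digit tract FIPS code."""


class TableFormatError(GistarError):
    """A tabular input violates the expected schema or value constraints."""


class IdMismatchError(GistarError):
    """Geometry and population table do not share the same identifier set."""

    def __init__(self, missing_in_population, missing_in_geometry):
        self.missing_in_population = sorted(missing_in_population)
        self.missing_in_geometry = sorted(missing_in_geometry)
        super().__init__(
            "identifier mismatch between geometry and population table; "
            f"geometry-only: {self.missing_in_population}, "
            f"population-only: {self.missing_in_geometry}"
        )


class OverlappingUnitsError(GistarError):
    """A tract's representative point lies inside two or more larger units."""

    def __init__(self, tract: str, unit_ids):
        self.tract = tract
        self.unit_ids = sorted(unit_ids)
        super().__init__(
            f"tract {tract!r} falls inside overlapping units {self.unit_ids}; "
            "larger-unit polygons must be non-overlapping"
        )


class ZeroVarianceError(GistarError):
    """All proportions in a unit are equal; the statistic is undefined."""

    def __init__(self, unit_id: str):
        self.unit_id = unit_id
        super().__init__(f"zero variance of proportions in unit {unit_id!r}")


class FullyConnectedError(GistarError):
    """A focal tract's weights row spans the whole unit (denominator 0)."""

    def __init__(self, tracts):
        self.tracts = sorted(tracts)
        super().__init__(
            f"degenerate denominator (tract connected to every other tract) "
            f"for: {self.tracts}"
        )
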