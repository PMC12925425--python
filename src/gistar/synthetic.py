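"""Synthetic lattice "cities": geometry, populations and degenerate cases.

Everything here is deterministic given its spec (and seed, where a seed
applies), so tests and the acceptance report can regenerate inputs instead
of shipping binary fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from .pipeline import (
    CODE_ALL_ISLANDS,
    CODE_FULLY_CONNECTED,
    CODE_NO_TARGET_POPULATION,
    CODE_SINGLE_TRACT,
    CODE_ZERO_POPULATION,
    INDICATOR_CODES,
)


@dataclass(frozen=True)
class LatticeSpec:
    """A rectangular grid of square tracts with minted FIPS identifiers."""

    nrows: int
    ncols: int
    cell_size: float = 1.0
    origin: tuple = (0.0, 0.0)
    state: str = "17"
    county: str = "031"

    def __post_init__(self):
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if self.nrows * self.ncols > 999_9:
            raise ValueError("lattice too large for the 6-digit tract space")

    def tract_id(self, r: int, c: int) -> str:
        seq = r * self.ncols + c + 1
        return f"{self.state}{self.county}{seq:04d}00"


def make_lattice(spec: LatticeSpec) -> dict:
    """Row-major dict of canonical FIPS id -> unit-square polygon."""
    x0, y0 = spec.origin
    s = spec.cell_size
    out = {}
    for r in range(spec.nrows):
        for c in range(spec.ncols):
            out[spec.tract_id(r, c)] = box(
                x0 + c * s, y0 + r * s, x0 + (c + 1) * s, y0 + (r + 1) * s
            )
    return out


@dataclass(frozen=True)
class PopulationScenario:
    """How group counts are drawn for a set of tracts.

    ``uniform`` draws every group at rate ``p_out`` everywhere;
    ``planted_cluster`` raises the *first* group to ``p_in`` inside the
    block ``(row0, col0, row1, col1)`` (half-open, lattice coordinates);
    ``islands`` is uniform (the geometry, not the population, makes
    islands).
    """

    scenario: str = "uniform"
    groups: Sequence[str] = ("nhWhite", "nhBlack", "nhAsian", "Hispanic")
    total: int = 1000
    block: tuple = (0, 0, 2, 2)
    p_in: float = 0.8
    p_out: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in ("uniform", "planted_cluster", "islands"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not self.groups:
            raise ValueError("at least one group required")


def make_population(
    ids: Sequence[str],
    scenario: PopulationScenario,
    spec: Optional[LatticeSpec] = None,
) -> pd.DataFrame:
    """Draw a reproducible population table for ``ids``.

    For ``planted_cluster``, ``spec`` locates each id on the lattice so the
    block can be resolved; the first group is binomial(total, p_in) inside
    the block and binomial(total, p_out) outside.  Remaining groups share
    the leftover population so per-tract group sums never exceed the total.

    Returns a DataFrame indexed by canonical FIPS with the group columns
    and ``"total"``.
    """
    rng = np.random.default_rng(scenario.seed)
    if scenario.scenario == "planted_cluster" and spec is None:
        raise ValueError("planted_cluster needs the LatticeSpec to locate the block")

    in_block = set()
    if scenario.scenario == "planted_cluster":
        r0, c0, r1, c1 = scenario.block
        for r in range(r0, r1):
            for c in range(c0, c1):
                in_block.add(spec.tract_id(r, c))
        unknown = in_block - set(ids)
        if unknown:
            raise ValueError(f"block tracts not in ids: {sorted(unknown)}")

    first, rest = scenario.groups[0], list(scenario.groups[1:])
    rows = []
    for tid in ids:
        total = scenario.total
        p = scenario.p_in if tid in in_block else scenario.p_out
        lead = int(rng.binomial(total, p))
        counts = {first: lead}
        if rest:
            # split part of the leftover so other groups stay comparable
            remaining = total - lead
            probs = [scenario.p_out] * len(rest) + [
                max(0.0, 1.0 - scenario.p_out * len(rest))
            ]
            draw = rng.multinomial(remaining, np.asarray(probs) / sum(probs))
            counts.update({g: int(draw[k]) for k, g in enumerate(rest)})
        rows.append({"FIPS_ID": tid, **counts, "total": total})
    df = pd.DataFrame(rows).set_index("FIPS_ID")
    return df[[*scenario.groups, "total"]]


def make_islands(
    n: int = 3, gap: float = 1.0, state: str = "17", county: str = "031"
) -> dict:
    """``n`` unit squares separated by ``gap`` (no shared boundary points)."""
    out = {}
    for k in range(n):
        x0 = k * (1.0 + gap)
        out[f"{state}{county}{k + 1:04d}00"] = box(x0, 0.0, x0 + 1.0, 1.0)
    return out


def make_degenerate_fixture(code: int, seed: int = 0) -> tuple:
    """Minimal (geometry, population, expectation) triple for one code.

    The expectation dict names the group/tracts whose Gstat cells must hold
    the code end-to-end, plus (for the no-target-population case) a control
    group expected to yield finite Z-scores.  Non-degenerate counts are
    drawn from ``seed`` so the fixture still exercises real data paths.
    """
    rng = np.random.default_rng(seed)

    def counts(nids, low=50, high=400):
        return rng.integers(low, high, size=nids)

    if code == CODE_SINGLE_TRACT:
        spec = LatticeSpec(1, 1)
        polygons = make_lattice(spec)
        ids = list(polygons)
        pop = pd.DataFrame(
            {"nhWhite": counts(1), "total": 1000}, index=pd.Index(ids, name="FIPS_ID")
        )
        expected = {"code": code, "group": "nhWhite", "tracts": ids}
    elif code == CODE_ZERO_POPULATION:
        spec = LatticeSpec(3, 3)
        polygons = make_lattice(spec)
        ids = list(polygons)
        empty = spec.tract_id(1, 1)
        totals = pd.Series(1000, index=ids)
        group = pd.Series(counts(9), index=ids)
        totals[empty] = 0
        group[empty] = 0
        pop = pd.DataFrame(
            {"nhWhite": group, "total": totals}, index=pd.Index(ids, name="FIPS_ID")
        )
        expected = {"code": code, "group": "nhWhite", "tracts": [empty]}
    elif code == CODE_NO_TARGET_POPULATION:
        # 4x4 so no tract is queen-adjacent to every other: the control
        # group's column must come out fully finite.
        spec = LatticeSpec(4, 4)
        polygons = make_lattice(spec)
        ids = list(polygons)
        pop = pd.DataFrame(
            {"nhWhite": 0, "nhBlack": counts(16), "total": 1000},
            index=pd.Index(ids, name="FIPS_ID"),
        )
        expected = {
            "code": code,
            "group": "nhWhite",
            "tracts": ids,
            "control_group": "nhBlack",
        }
    elif code == CODE_FULLY_CONNECTED:
        spec = LatticeSpec(2, 2)
        polygons = make_lattice(spec)
        ids = list(polygons)
        pop = pd.DataFrame(
            {"nhWhite": counts(4), "total": 1000}, index=pd.Index(ids, name="FIPS_ID")
        )
        expected = {"code": code, "group": "nhWhite", "tracts": ids}
    elif code == CODE_ALL_ISLANDS:
        polygons = make_islands(3)
        ids = list(polygons)
        pop = pd.DataFrame(
            {"nhWhite": counts(3), "total": 1000}, index=pd.Index(ids, name="FIPS_ID")
        )
        expected = {"code": code, "group": "nhWhite", "tracts": ids}
    else:
        raise ValueError(f"unknown indicator code {code}; known: {INDICATOR_CODES}")

    return polygons, pop, expected
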