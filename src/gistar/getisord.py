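"""Standardized local Getis-Ord Gi* for group proportions within one unit.

The "star" form counts the focal tract as its own neighbor; with
self-included, row-standardized weights the statistic for focal tract ``i``
in a unit of ``n`` tracts is

    Gi* = (sum_j w_ij x_j - x_bar * W_i)
          / ( s * sqrt( (n * S1_i - W_i^2) / (n - 1) ) )

where ``W_i = sum_j w_ij``, ``S1_i = sum_j w_ij^2``, and ``x_bar`` and the
population standard deviation ``s`` are taken over all ``n`` tracts of the
unit, focal included.  Positive Z-scores mean the focal tract and its
neighbors are overrepresented for the group relative to the unit mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Mapping

import numpy as np

from .contiguity import WeightsRow
from .errors import FullyConnectedError, TableFormatError, ZeroVarianceError


@dataclass(eq=False)
class GroupProportionVector:
    """Group proportions for the tracts of one areal unit.

    Attributes
    ----------
    unit_id : str
        Identifier of the larger areal unit.
    x : mapping of tract id -> proportion in [0, 1]
        One entry per tract that has population (zero-total tracts are
        excluded before construction).
    """

    unit_id: str
    x: Mapping[str, float]

    def __post_init__(self):
        for tid, v in self.x.items():
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValueError(f"proportion out of [0, 1] for tract {tid!r}: {v}")

    @property
    def n(self) -> int:
        return len(self.x)

    @cached_property
    def _values(self) -> np.ndarray:
        return np.asarray(list(self.x.values()), dtype=float)

    @cached_property
    def x_bar(self) -> float:
        """Mean proportion over all n tracts."""
        return float(self._values.mean())

    @cached_property
    def s(self) -> float:
        """Population standard deviation sqrt(E[x^2] - x_bar^2)."""
        v = self._values
        return float(np.sqrt(max((v * v).mean() - self.x_bar**2, 0.0)))


def compute_group_proportions(
    counts: Mapping[str, int],
    totals: Mapping[str, int],
    unit_id: str = "",
) -> tuple[GroupProportionVector, frozenset]:
    """Build the proportion vector for one group, flagging zero-total tracts.

    Parameters
    ----------
    counts, totals : mapping of tract id -> non-negative int
        Group count and total population per tract; identically keyed.
    unit_id : str
        Carried onto the returned vector.

    Returns
    -------
    (GroupProportionVector, frozenset)
        Proportions ``counts/totals`` over tracts with positive totals, and
        the set of tract ids with total 0 (excluded from the vector; they
        receive the zero-population indicator code downstream).

    Raises
    ------
    TableFormatError
        If the keys differ, any value is negative, or a count exceeds its
        total (the offending tract id is reported).
    """
    if set(counts) != set(totals):
        raise TableFormatError("counts and totals must be keyed identically")
    zero_total = set()
    x = {}
    for tid in counts:
        c, t = counts[tid], totals[tid]
        if c < 0 or t < 0:
            raise TableFormatError(f"negative value for tract {tid!r}")
        if c > t:
            raise TableFormatError(f"count exceeds total for tract {tid!r}: {c} > {t}")
        if t == 0:
            zero_total.add(tid)
        else:
            x[tid] = c / t
    return GroupProportionVector(unit_id=unit_id, x=x), frozenset(zero_total)


def gi_star_unit(
    xv: GroupProportionVector,
    weights: Mapping[str, WeightsRow],
    strict: bool = True,
) -> dict:
    """Standardized Gi* Z-score for every tract of one unit.

    Parameters
    ----------
    xv : GroupProportionVector
        Proportions for all ``n`` tracts of the unit (``n >= 2``).
    weights : mapping of tract id -> WeightsRow
        Self-included weights rows; every referenced tract must belong to
        the unit.
    strict : bool
        Behavior for a focal tract with a degenerate denominator
        (``n * S1_i - W_i^2 <= 0``, i.e. connected to every other tract).
        When the numerator also vanishes — which it does by construction
        for equal self-included weights spanning the whole unit, since the
        lag then equals the unit mean — the tract's neighborhood shows no
        deviation and the statistic is returned as exactly 0.0.  Otherwise
        True (default) raises :class:`FullyConnectedError` and False
        silently omits the tract so the caller can code it.

    Returns
    -------
    dict of tract id -> float

    Raises
    ------
    ZeroVarianceError
        If all proportions are equal (``s = 0``).
    FullyConnectedError
        See ``strict``.
    """
    n = xv.n
    if n < 2:
        raise ValueError(f"unit {xv.unit_id!r} needs at least 2 tracts, got {n}")
    if xv.s == 0.0:
        raise ZeroVarianceError(xv.unit_id)

    ids = list(xv.x)
    index = {tid: k for k, tid in enumerate(ids)}
    x = xv._values

    W = np.empty(n)
    S1 = np.empty(n)
    lag = np.empty(n)
    for tid in ids:
        row = weights[tid]
        k = index[tid]
        try:
            cols = [index[j] for j in row.weights]
        except KeyError as exc:
            raise ValueError(
                f"weights row of {tid!r} references tract {exc.args[0]!r} "
                f"outside unit {xv.unit_id!r}"
            ) from None
        wv = np.asarray(list(row.weights.values()), dtype=float)
        W[k] = wv.sum()
        S1[k] = (wv * wv).sum()
        lag[k] = (wv * x[cols]).sum()

    inner = (n * S1 - W * W) / (n - 1)
    numer = lag - xv.x_bar * W
    # the smallest genuinely positive inner term is 1/(n-1)^2 (focal row
    # one member short of the unit), so 1e-12 only absorbs rounding noise
    # of the exactly-degenerate equal-full-span case
    collapsed = inner <= 1e-12
    degenerate = collapsed & (np.abs(numer) > 1e-12)
    zero_limit = collapsed & ~degenerate
    if degenerate.any() and strict:
        raise FullyConnectedError([ids[k] for k in np.flatnonzero(degenerate)])

    with np.errstate(invalid="ignore", divide="ignore"):
        z = numer / (xv.s * np.sqrt(inner))
    z[zero_limit] = 0.0
    return {tid: float(z[index[tid]]) for tid in ids if not degenerate[index[tid]]}
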