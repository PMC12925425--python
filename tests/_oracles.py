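"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's code paths: adjacency is decided
from pairwise DE-9IM relate strings in a full O(N^2) double loop, and the
statistic is evaluated by dense direct summation in pure Python.
"""

from __future__ import annotations

import itertools
import math


def adjacency_oracle(polygons: dict, mode: str) -> dict:
    """All-pairs contiguity from DE-9IM patterns (no spatial index)."""
    ids = list(polygons)
    neighbors = {i: set() for i in ids}
    for a, b in itertools.combinations(ids, 2):
        pattern = polygons[a].relate(polygons[b])
        # DE-9IM string order: II IB IE BI BB BE EI EB EE
        share_any_point = any(pattern[k] != "F" for k in (0, 1, 3, 4))
        share_edge = pattern[4] == "1"
        hit = share_edge if mode == "rook" else share_any_point
        if hit:
            neighbors[a].add(b)
            neighbors[b].add(a)
    return neighbors


def gi_star_dense(x: dict, weights: dict) -> dict:
    """Dense double-loop evaluation of the standardized Gi* formula.

    ``weights[i]`` maps neighbor ids (including i) to w_ij; absent pairs
    have weight zero.  Returns None for a focal unit whose denominator
    term n*S1 - W^2 is non-positive.
    """
    ids = list(x)
    n = len(ids)
    x_bar = sum(x[i] for i in ids) / n
    s = math.sqrt(sum(x[i] ** 2 for i in ids) / n - x_bar**2)
    out = {}
    for i in ids:
        W = 0.0
        S1 = 0.0
        lag = 0.0
        for j in ids:
            w = weights[i].get(j, 0.0)
            W += w
            S1 += w * w
            lag += w * x[j]
        inner = (n * S1 - W * W) / (n - 1)
        # mathematically inner >= 0 with equality only for an equal
        # full-span row (Cauchy-Schwarz); absorb rounding noise of that
        # exactly-zero case
        if inner <= 1e-12:
            out[i] = None
            continue
        out[i] = (lag - x_bar * W) / (s * math.sqrt(inner))
    return out
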