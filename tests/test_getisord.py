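import math

import numpy as np
import pytest
from shapely.geometry import box

from _oracles import gi_star_dense
from conftest import perturbed_lattice
from gistar.contiguity import build_neighbor_graph, row_standardize_with_self
from gistar.errors import TableFormatError, ZeroVarianceError
from gistar.getisord import (
    GroupProportionVector,
    compute_group_proportions,
    gi_star_unit,
)

CHAIN = {"a": box(0, 0, 1, 1), "b": box(1, 0, 2, 1), "c": box(2, 0, 3, 1)}


def chain_weights():
    return row_standardize_with_self(build_neighbor_graph(CHAIN, "rook"))


class TestProportions:
    def test_basic_arithmetic(self):
        xv, flagged = compute_group_proportions({"a": 30}, {"a": 100})
        assert xv.x == {"a": 0.3}
        assert flagged == frozenset()

    def test_zero_total_flagged_and_excluded(self):
        xv, flagged = compute_group_proportions(
            {"a": 30, "b": 0}, {"a": 100, "b": 0}
        )
        assert flagged == {"b"}
        assert set(xv.x) == {"a"}
        assert xv.n == 1

    def test_full_group_boundary(self):
        xv, _ = compute_group_proportions({"a": 100}, {"a": 100})
        assert xv.x["a"] == 1.0

    def test_rejects_count_over_total(self):
        with pytest.raises(TableFormatError, match="'b'"):
            compute_group_proportions({"a": 1, "b": 120}, {"a": 10, "b": 100})

    def test_rejects_negative(self):
        with pytest.raises(TableFormatError):
            compute_group_proportions({"a": -1}, {"a": 10})

    def test_rejects_key_mismatch(self):
        with pytest.raises(TableFormatError):
            compute_group_proportions({"a": 1}, {"b": 10})

    def test_moments_match_recomputation(self, rng):
        x = {f"t{k}": float(v) for k, v in enumerate(rng.uniform(0, 1, 20))}
        xv = GroupProportionVector("u", x)
        vals = np.array(list(x.values()))
        assert xv.x_bar == pytest.approx(vals.mean(), abs=1e-12)
        assert xv.s == pytest.approx(vals.std(), abs=1e-12)
        assert xv.s >= 0

    def test_s_zero_iff_constant(self):
        assert GroupProportionVector("u", {"a": 0.4, "b": 0.4}).s == 0.0
        assert GroupProportionVector("u", {"a": 0.4, "b": 0.5}).s > 0.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            GroupProportionVector("u", {"a": 1.5})


class TestChainValues:
    """Hand-derived 3-chain: x = (1, 0, 0) -> (1/sqrt2, 0, -sqrt2)."""

    def test_hand_derived_values(self):
        xv = GroupProportionVector("u", {"a": 1.0, "b": 0.0, "c": 0.0})
        z = gi_star_unit(xv, chain_weights())
        assert z["a"] == pytest.approx(0.70711, abs=1e-5)
        assert z["b"] == pytest.approx(0.0, abs=1e-5)
        assert z["c"] == pytest.approx(-1.41421, abs=1e-5)

    def test_agrees_with_dense_oracle(self):
        xv = GroupProportionVector("u", {"a": 1.0, "b": 0.0, "c": 0.0})
        z = gi_star_unit(xv, chain_weights())
        oracle = gi_star_dense(xv.x, {t: dict(r.weights) for t, r in chain_weights().items()})
        for t in ("a", "c"):
            assert z[t] == pytest.approx(oracle[t], abs=1e-12)


class TestErrors:
    def test_zero_variance_raises(self):
        xv = GroupProportionVector("u", {"a": 0.4, "b": 0.4, "c": 0.4})
        with pytest.raises(ZeroVarianceError):
            gi_star_unit(xv, chain_weights())

    def test_single_tract_unit_rejected(self):
        xv = GroupProportionVector("u", {"a": 0.4})
        with pytest.raises(ValueError):
            gi_star_unit(xv, {"a": chain_weights()["a"]})

    def test_weights_outside_unit_rejected(self):
        xv = GroupProportionVector("u", {"a": 0.1, "b": 0.9})
        with pytest.raises(ValueError, match="outside unit"):
            gi_star_unit(xv, chain_weights())

    def test_zero_numerator_full_connection_returns_limit(self):
        # equal self-included weights spanning the unit: lag == mean,
        # the 0/0 case resolves to "no deviation".  By Cauchy-Schwarz,
        # n*S1 - W^2 <= 0 forces exactly this equal-full-span shape, so
        # the limit (not FullyConnectedError) is what real inputs hit.
        xv = GroupProportionVector("u", {"a": 1.0, "b": 0.0, "c": 0.0})
        assert gi_star_unit(xv, chain_weights())["b"] == 0.0
        # same limit when the equal full-span row is not row-standardized
        from gistar.contiguity import WeightsRow

        weights = dict(chain_weights())
        weights["b"] = WeightsRow("b", {"a": 0.2, "b": 0.2, "c": 0.2})
        assert gi_star_unit(xv, weights)["b"] == 0.0


def random_unit(rng, max_side=7):
    polys = perturbed_lattice(
        int(rng.integers(2, max_side)), int(rng.integers(2, max_side)), rng
    )
    mode = rng.choice(["queen", "rook"])
    weights = row_standardize_with_self(build_neighbor_graph(polys, mode))
    x = {t: float(p) for t, p in zip(polys, rng.uniform(0, 1, len(polys)))}
    return GroupProportionVector("u", x), weights


class TestProperties:
    def test_oracle_equivalence_random_units(self, rng):
        for _ in range(40):
            xv, weights = random_unit(rng)
            z = gi_star_unit(xv, weights, strict=False)
            oracle = gi_star_dense(xv.x, {t: dict(r.weights) for t, r in weights.items()})
            for t, expect in oracle.items():
                if expect is None:
                    continue
                assert z[t] == pytest.approx(expect, abs=1e-10)

    def test_location_scale_invariance(self, rng):
        for _ in range(10):
            xv, weights = random_unit(rng)
            a, b = rng.uniform(0.0, 0.3), rng.uniform(0.1, 0.7)
            shifted = GroupProportionVector("u", {t: a + b * v for t, v in xv.x.items()})
            z0 = gi_star_unit(xv, weights, strict=False)
            z1 = gi_star_unit(shifted, weights, strict=False)
            assert set(z0) == set(z1)
            for t in z0:
                assert z1[t] == pytest.approx(z0[t], abs=1e-9)

    def test_permutation_equivariance(self, rng):
        xv, weights = random_unit(rng)
        ids = list(xv.x)
        relabel = dict(zip(ids, rng.permutation(ids)))
        from gistar.contiguity import WeightsRow

        xv2 = GroupProportionVector("u", {relabel[t]: v for t, v in xv.x.items()})
        weights2 = {
            relabel[t]: WeightsRow(
                relabel[t], {relabel[j]: w for j, w in row.weights.items()}
            )
            for t, row in weights.items()
        }
        z = gi_star_unit(xv, weights, strict=False)
        z2 = gi_star_unit(xv2, weights2, strict=False)
        assert set(z2) == {relabel[t] for t in z}
        for t in z:
            assert z2[relabel[t]] == pytest.approx(z[t], abs=1e-12)

    def test_planted_block_signs(self, rng):
        from gistar.synthetic import LatticeSpec, make_lattice

        spec = LatticeSpec(6, 6)
        polys = make_lattice(spec)
        weights = row_standardize_with_self(build_neighbor_graph(polys, "queen"))
        block = {spec.tract_id(r, c) for r in range(2) for c in range(2)}
        x = {t: (0.9 if t in block else 0.05) for t in polys}
        z = gi_star_unit(GroupProportionVector("u", x), weights)
        oracle = gi_star_dense(x, {t: dict(r.weights) for t, r in weights.items()})
        for t in block:
            assert z[t] > 0 and oracle[t] > 0
        far = spec.tract_id(5, 5)
        assert z[far] < 0 and oracle[far] < 0
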