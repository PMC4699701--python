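"""Topographic product and permutation normalization against oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_topographic_product
from lgncolumns import normalized_pt, order_pvalue, topographic_product
from lgncolumns.errors import (
    DegenerateGeometryError,
    MissingInjectionError,
    ZeroDistanceError,
)
from lgncolumns.maps import make_percentile_map
from lgncolumns.order import end_to_end_order, topography_profile, topology_profile


def _random_config(rng, n, d=2, scale=10.0):
    return rng.normal(0, scale, (n, d))


class TestRawProduct:
    def test_identical_spaces_give_zero(self):
        a = _random_config(np.random.default_rng(0), 10)
        assert topographic_product(a, a) == 0.0

    def test_uniform_scaling_gives_zero(self):
        a = _random_config(np.random.default_rng(1), 8)
        assert topographic_product(a, a * 3.0) == 0.0

    def test_line_with_swapped_labels_matches_hand_computation(self):
        a = np.column_stack([np.arange(5.0), np.zeros(5)])
        b = a.copy()
        b[[1, 3]] = b[[3, 1]]  # swap two labels
        assert topographic_product(a, b) == pytest.approx(
            brute_force_topographic_product(a, b), abs=1e-12
        )

    def test_antisymmetric_under_space_exchange(self):
        rng = np.random.default_rng(2)
        for n in (4, 6, 9):
            a, b = _random_config(rng, n), _random_config(rng, n)
            assert topographic_product(a, b) == pytest.approx(
                -topographic_product(b, a), abs=1e-12
            )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 7))
    def test_matches_brute_force_oracle(self, seed, n):
        """Vectorised product equals the explicit double sum, N ≤ 7."""
        rng = np.random.default_rng(seed)
        a, b = _random_config(rng, n), _random_config(rng, n, d=3)
        assert topographic_product(a, b) == pytest.approx(
            brute_force_topographic_product(a, b), abs=1e-10
        )

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_similarity_invariance(self, seed):
        """Rotation, translation and scaling of either space change nothing."""
        rng = np.random.default_rng(seed)
        a, b = _random_config(rng, 8), _random_config(rng, 8)
        phi = rng.uniform(-np.pi, np.pi)
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        b2 = 2.5 * b @ R.T + rng.uniform(-5, 5, 2)
        assert topographic_product(a, b2) == pytest.approx(
            topographic_product(a, b), abs=1e-10
        )

    def test_coincident_points_rejected_and_jitter_opt_in(self):
        a = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        b = _random_config(np.random.default_rng(3), 4)
        with pytest.raises(ZeroDistanceError):
            topographic_product(a, b)
        result = normalized_pt(a, b, n_perm=99, seed=0, jitter=True)
        assert np.isfinite(result.normalized_pt)


class TestNormalizedPt:
    def test_identical_maps_give_exact_zero_any_seed(self):
        a = _random_config(np.random.default_rng(4), 9)
        for seed in (0, 1, 99):
            assert normalized_pt(a, a, n_perm=99, seed=seed).normalized_pt == 0.0

    def test_random_relabelling_averages_one(self):
        rng = np.random.default_rng(5)
        a = _random_config(rng, 10)
        values = [
            normalized_pt(a, a[rng.permutation(10)], n_perm=199, seed=rng).normalized_pt
            for _ in range(60)
        ]
        assert np.mean(values) == pytest.approx(1.0, abs=0.15)

    def test_six_point_enumeration_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(60)
        a = rng.normal(0, 10, (6, 2))
        b = rng.normal(0, 10, (6, 2))
        result = normalized_pt(a, b, n_perm=720, seed=0)
        assert result.n_perm == 720
        obs = abs(brute_force_topographic_product(a, b))
        perm_abs = [
            abs(brute_force_topographic_product(a, b[list(p)]))
            for p in itertools.permutations(range(6))
        ]
        assert result.normalized_pt == pytest.approx(obs / np.mean(perm_abs), abs=1e-10)
        n_le = sum(p <= obs for p in perm_abs)
        assert result.p_value == pytest.approx((1 + n_le) / 721, abs=1e-12)

    def test_monte_carlo_converges_to_enumeration(self):
        rng = np.random.default_rng(6)
        a = _random_config(rng, 6)
        b = _random_config(rng, 6)
        exact = normalized_pt(a, b, n_perm=720, seed=0)
        approx = normalized_pt(a, b, n_perm=599, seed=7)
        assert approx.normalized_pt == pytest.approx(exact.normalized_pt, rel=0.15)
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.1)

    def test_min_permutations_enforced(self):
        a = _random_config(np.random.default_rng(7), 5)
        with pytest.raises(DegenerateGeometryError):
            normalized_pt(a, a, n_perm=50)


class TestPValue:
    def test_perfect_order_gives_minimum_p(self):
        a = _random_config(np.random.default_rng(8), 10)
        assert order_pvalue(a, 2.0 * a, n_perm=99, seed=1) == pytest.approx(0.01)

    def test_worst_enumerable_config_gives_p_one(self):
        rng = np.random.default_rng(9)
        a = _random_config(rng, 5)
        b = _random_config(rng, 5)
        # pick the least ordered relabelling as the observation
        perms = list(itertools.permutations(range(5)))
        worst = max(perms, key=lambda p: abs(topographic_product(a, b[list(p)])))
        assert order_pvalue(a, b[list(worst)], n_perm=120, seed=0) == 1.0

    def test_null_p_values_center_near_half(self):
        rng = np.random.default_rng(10)
        a = _random_config(rng, 8)
        ps = [
            order_pvalue(a, _random_config(rng, 8), n_perm=99, seed=rng)
            for _ in range(200)
        ]
        assert 0.4 < np.mean(ps) < 0.6


class TestStackProfiles:
    @staticmethod
    def _stack(layers):
        stack = []
        for depth, pts in layers:
            ids = [f"c{i}" for i in range(len(pts))]
            stack.append(make_percentile_map(dict(zip(ids, np.asarray(pts))), depth))
        return stack

    def _translated_stack(self, n_levels=5, n=9, seed=11):
        rng = np.random.default_rng(seed)
        base = np.column_stack([rng.normal(0, 100, (n, 2)), np.zeros(n)])
        return self._stack(
            [(k / (n_levels - 1), base + [0, 0, 150 * k]) for k in range(n_levels)]
        )

    def test_translated_copies_perfectly_ordered(self):
        results = topology_profile(self._translated_stack(), n_perm=99, seed=0)
        assert [r.normalized_pt for r in results] == [0.0] * 4

    def test_end_to_end_similarity_is_ordered(self):
        rng = np.random.default_rng(12)
        base = np.column_stack([rng.normal(0, 100, (10, 2)), np.zeros(10)])
        phi = 0.8
        R2 = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        top = np.column_stack([1.7 * base[:, :2] @ R2.T, np.full(10, 400.0)])
        stack = self._stack([(0.0, base), (1.0, top)])
        result = end_to_end_order(stack, n_perm=99, seed=3)
        assert result.normalized_pt == pytest.approx(0.0, abs=1e-12)
        assert result.p_value <= 0.01

    def test_three_shared_columns_flagged_low_n(self):
        rng = np.random.default_rng(13)
        base = np.column_stack([rng.normal(0, 100, (3, 2)), np.zeros(3)])
        stack = self._stack([(0.0, base), (1.0, base + [0, 0, 300])])
        result = end_to_end_order(stack, n_perm=99, seed=0)
        assert result.low_n

    def test_topography_similarity_and_shuffled(self):
        rng = np.random.default_rng(14)
        stack = self._translated_stack(n_levels=3, n=10, seed=14)
        ids = stack[0].animal_ids
        # injections: a similarity image of the map coordinates
        inj = {a: 0.004 * stack[0].coords_for([a])[0] + [1.0, -2.0] for a in ids}
        results = topography_profile(inj, stack, n_perm=99, seed=0)
        assert results[0].normalized_pt == pytest.approx(0.0, abs=1e-12)
        shuffled_vals = []
        for _ in range(40):
            perm = rng.permutation(len(ids))
            shuffled = {a: inj[ids[perm[i]]] for i, a in enumerate(ids)}
            res = topography_profile(shuffled, stack, n_perm=99, seed=rng)
            shuffled_vals.append(res[0].normalized_pt)
        assert np.mean(shuffled_vals) == pytest.approx(1.0, abs=0.25)

    def test_missing_injection_named(self):
        stack = self._translated_stack(n_levels=2)
        inj = {a: np.zeros(2) for a in stack[0].animal_ids[:-1]}
        with pytest.raises(MissingInjectionError, match="c8"):
            topography_profile(inj, stack, n_perm=99, seed=0)
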