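"""Topographic-product order metrics with permutation normalization.

The topographic product compares neighbourhood structure between two
matched point configurations (Bauer & Pawelzik's graph-based map-order
measure).  For each point j and neighbour rank k, with d_a/d_b the
distances in the two spaces and n_k^a(j)/n_k^b(j) the k-th nearest
neighbour of j in each space,

    Q1(j, k) = d_b(j, n_k^a(j)) / d_b(j, n_k^b(j))
    Q2(j, k) = d_a(j, n_k^a(j)) / d_a(j, n_k^b(j))
    P = 1/(N(N-1)) · Σ_j Σ_k log[ (Π_{l≤k} Q1(j,l)·Q2(j,l))^(1/2k) ]

P is exactly 0 when both spaces share the same neighbour ranks and is
invariant under similarity transforms of either space.  Exchanging the two
spaces flips its sign, so magnitude |P| is what carries order information.

Because raw P has no absolute scale, it is normalized to the mean |P| of
random relabellings of one space: normalized P_t = 0 means perfect order
and ≈ 1 the disorder expected by chance (values above 1 are possible and
reported unclipped).  The Monte-Carlo permutation p-value is
(1 + #{|P_perm| ≤ |P_obs|}) / (1 + n_perm).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import DegenerateGeometryError, MissingInjectionError, ZeroDistanceError
from .maps import PercentileMap

DEFAULT_N_PERM = 999
LOW_N_THRESHOLD = 4  # n_points below this are flagged as low-n results


def _distance_matrix(points: np.ndarray, label: str, jitter_rng=None) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 3:
        raise DegenerateGeometryError("need at least 3 matched points")
    D = squareform(pdist(points))
    off = ~np.eye(len(points), dtype=bool)
    if (D[off] == 0).any():
        if jitter_rng is None:
            raise ZeroDistanceError(
                f"coincident points in space {label!r}; pass jitter=True to "
                "break ties deterministically"
            )
        diameter = float(D.max())
        points = points + jitter_rng.normal(0.0, 1e-6 * max(diameter, 1.0), points.shape)
        D = squareform(pdist(points))
        if (D[off] == 0).any():  # pragma: no cover
            raise ZeroDistanceError(f"space {label!r} still degenerate after jitter")
    return D


def _pt_from_distances(DA: np.ndarray, DB: np.ndarray) -> float:
    """Raw topographic product from two pre-computed distance matrices."""
    N = len(DA)
    # stable argsort: the self-distance 0 sorts first; ties broken by index
    order_a = np.argsort(DA, axis=1, kind="stable")[:, 1:]
    order_b = np.argsort(DB, axis=1, kind="stable")[:, 1:]
    rows = np.arange(N)[:, None]
    logQ1 = np.log(DB[rows, order_a]) - np.log(DB[rows, order_b])
    logQ2 = np.log(DA[rows, order_a]) - np.log(DA[rows, order_b])
    cum = np.cumsum(logQ1 + logQ2, axis=1)
    k = np.arange(1, N)
    return float(np.sum(cum / (2.0 * k)) / (N * (N - 1)))


def topographic_product(space_a: np.ndarray, space_b: np.ndarray) -> float:
    """Raw topographic product P between two matched point configurations."""
    DA = _distance_matrix(space_a, "a")
    DB = _distance_matrix(space_b, "b")
    if len(DA) != len(DB):
        raise DegenerateGeometryError("spaces must contain the same number of points")
    return _pt_from_distances(DA, DB)


@dataclass
class OrderResult:
    """Raw and permutation-normalized topographic product with its p-value."""

    raw_product: float
    normalized_pt: float
    p_value: float
    n_points: int
    n_perm: int
    seed: int | None
    low_n: bool
    depth: float | None = None
    comparison: str = ""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _permutations(n: int, n_perm: int, rng: np.random.Generator):
    """All n! relabellings when enumerable within n_perm, else Monte Carlo."""
    if factorial(n) <= n_perm:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        return perms, True
    return [rng.permutation(n) for _ in range(n_perm)], False


def normalized_pt(
    space_a,
    space_b,
    n_perm: int = DEFAULT_N_PERM,
    seed=None,
    jitter: bool = False,
) -> OrderResult:
    """Permutation-normalized topographic product between matched spaces.

    The label permutation is applied to space b.  When n! ≤ n_perm the
    full permutation group is enumerated instead of sampled, making the
    normalization and p-value exact.
    """
    if n_perm < 99:
        raise DegenerateGeometryError("n_perm must be at least 99")
    rng = _as_rng(seed)
    jit = rng if jitter else None
    DA = _distance_matrix(space_a, "a", jitter_rng=jit)
    DB = _distance_matrix(space_b, "b", jitter_rng=jit)
    if len(DA) != len(DB):
        raise DegenerateGeometryError("spaces must contain the same number of points")
    N = len(DA)
    p_obs = _pt_from_distances(DA, DB)
    perms, _exhaustive = _permutations(N, n_perm, rng)
    abs_perm = np.empty(len(perms))
    for i, perm in enumerate(perms):
        abs_perm[i] = abs(_pt_from_distances(DA, DB[np.ix_(perm, perm)]))
    mean_abs = float(abs_perm.mean())
    if mean_abs == 0.0:
        raise DegenerateGeometryError(
            "mean |P| over permutations is zero; normalization undefined"
        )
    n_eff = len(perms)
    p_value = (1 + int((abs_perm <= abs(p_obs)).sum())) / (1 + n_eff)
    return OrderResult(
        raw_product=p_obs,
        normalized_pt=abs(p_obs) / mean_abs,
        p_value=float(p_value),
        n_points=N,
        n_perm=n_eff,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        low_n=N < LOW_N_THRESHOLD,
    )


def order_pvalue(space_a, space_b, n_perm: int = DEFAULT_N_PERM, seed=None) -> float:
    """Monte-Carlo probability of a permutation at least as ordered."""
    return normalized_pt(space_a, space_b, n_perm=n_perm, seed=seed).p_value


# ---------------------------------------------------------------------------
# profiles over the map stack


def _shared_coords(map_a: PercentileMap, map_b: PercentileMap):
    shared = sorted(set(map_a.animal_ids) & set(map_b.animal_ids))
    if len(shared) < 3:
        raise DegenerateGeometryError(
            f"maps at depths {map_a.depth:g}/{map_b.depth:g} share only "
            f"{len(shared)} columns; need at least 3"
        )
    return map_a.coords_for(shared), map_b.coords_for(shared)


def _spawn_rngs(seed, n: int) -> list[np.random.Generator]:
    if isinstance(seed, np.random.Generator):
        return [np.random.default_rng(int(seed.integers(2**63))) for _ in range(n)]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def topology_profile(
    maps: list[PercentileMap], n_perm: int = DEFAULT_N_PERM, seed=None
) -> list[OrderResult]:
    """Order between each depth map and its predecessor (internal topology)."""
    rngs = _spawn_rngs(seed, len(maps) - 1)
    results = []
    for i in range(1, len(maps)):
        a, b = _shared_coords(maps[i - 1], maps[i])
        res = normalized_pt(a, b, n_perm=n_perm, seed=rngs[i - 1])
        res.depth = maps[i].depth
        res.comparison = "topology"
        results.append(res)
    return results


def end_to_end_order(
    maps: list[PercentileMap], n_perm: int = DEFAULT_N_PERM, seed=None
) -> OrderResult:
    """Order between the pial (first) and ventral (last) maps."""
    a, b = _shared_coords(maps[0], maps[-1])
    res = normalized_pt(a, b, n_perm=n_perm, seed=_as_rng(seed))
    res.depth = maps[-1].depth
    res.comparison = "end_to_end"
    return res


def topography_profile(
    injections: dict[str, np.ndarray],
    maps: list[PercentileMap],
    n_perm: int = DEFAULT_N_PERM,
    seed=None,
) -> list[OrderResult]:
    """Order between the V1 injection configuration and each depth map."""
    rngs = _spawn_rngs(seed, len(maps))
    results = []
    for i, m in enumerate(maps):
        missing = [a for a in m.animal_ids if a not in injections]
        if missing:
            raise MissingInjectionError(
                f"no injection coordinates for mapped columns {missing}"
            )
        v1 = np.array([injections[a] for a in m.animal_ids], dtype=float)
        res = normalized_pt(v1, m.coords, n_perm=n_perm, seed=rngs[i])
        res.depth = m.depth
        res.comparison = "topography"
        results.append(res)
    return results
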