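"""Shared fixtures: meshes, synthetic datasets, reference oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
import trimesh

from lgncolumns import NucleusMesh, SyntheticConfig, make_columns, make_mesh


@pytest.fixture(scope="session")
def sphere_mesh() -> NucleusMesh:
    """Radius-500 µm icosphere with the top (+y) cap labelled pial."""
    unit = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    centroids = unit.vertices[unit.faces].mean(axis=1)
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    polar = np.degrees(np.arccos(np.clip(centroids[:, 1], -1, 1)))
    return NucleusMesh(unit.vertices * 500.0, unit.faces, np.nonzero(polar < 55.0)[0])


@pytest.fixture(scope="session")
def default_mesh() -> NucleusMesh:
    return make_mesh(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def wt_dataset(default_mesh):
    """One synthetic wild-type-like group at the default study conditions."""
    config = SyntheticConfig(seed=5)
    dataset, truth = make_columns(config, default_mesh)
    return config, dataset, truth


def brute_force_topographic_product(a: np.ndarray, b: np.ndarray) -> float:
    """Independent reference: explicit double sum over points and ranks.

    Written with plain loops and sorted neighbour lists so it shares no
    code path with the vectorised implementation it checks.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = len(a)

    def dist(x, i, j):
        return math.dist(tuple(x[i]), tuple(x[j]))

    def neighbours(x, j):
        others = [i for i in range(n) if i != j]
        return sorted(others, key=lambda i: (dist(x, j, i), i))

    total = 0.0
    for j in range(n):
        na = neighbours(a, j)
        nb = neighbours(b, j)
        log_prod = 0.0
        for k in range(1, n):
            q1 = dist(b, j, na[k - 1]) / dist(b, j, nb[k - 1])
            q2 = dist(a, j, na[k - 1]) / dist(a, j, nb[k - 1])
            log_prod += math.log(q1) + math.log(q2)
            total += log_prod / (2 * k)
    return total / (n * (n - 1))
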