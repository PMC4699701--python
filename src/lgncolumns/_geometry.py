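"""Vectorized ray–triangle intersection and point containment.

Nucleus meshes are small (≈ 10³ faces), so brute force over all faces is
both fast and free of spatial-index dependencies.  Rays use the
Möller–Trumbore algorithm; containment uses crossing-number parity along
a fixed irrational-looking direction to dodge edge/vertex grazing.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12
# deliberately incommensurate with the icosphere symmetry axes
_PARITY_DIRECTION = np.array([0.5773502691896258, 0.6172133998483676, 0.5345224838248488])


def ray_intersections(
    vertices: np.ndarray, faces: np.ndarray, origin: np.ndarray, direction: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All forward intersections of one ray with a triangle soup.

    Returns (distances, face_indices, points) sorted by distance; only
    crossings with distance > 1e-9 count (the origin itself is excluded).
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    tri = vertices[faces]  # (F, 3, 3)
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > _EPS
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin - tri[:, 0]
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", direction, qvec) * inv_det
    t = np.einsum("ij,ij->i", e2, qvec) * inv_det
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-9)
    idx = np.nonzero(hit)[0]
    order = np.argsort(t[idx], kind="stable")
    idx = idx[order]
    distances = t[idx]
    points = origin + distances[:, None] * direction
    return distances, idx, points


def contains(vertices: np.ndarray, faces: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Crossing-parity containment test for each query point."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    inside = np.empty(len(points), dtype=bool)
    for i, p in enumerate(points):
        distances, _, _ = ray_intersections(vertices, faces, p, _PARITY_DIRECTION)
        # collapse duplicate hits from shared edges
        if len(distances):
            uniq = np.concatenate([[True], np.diff(distances) > 1e-9])
            n_hits = int(uniq.sum())
        else:
            n_hits = 0
        inside[i] = n_hits % 2 == 1
    return inside
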