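"""Per-depth 2D maps of column positions and their similarity alignment.

At each 5th-percentile depth the columns' iso-percentile 3D points are
projected onto their total-least-squares plane, giving a stack of 21 2D
maps.  Neighbouring maps are registered with a constrained similarity
transform (expansion E, rotation θ, translation), initialised at the
closed-form 2D similarity Procrustes solution; cumulative rotation and
expansion relative to the pial map summarise the trajectory of the whole
column system through the nucleus.

Rotation sign convention: θ is counter-clockwise positive when viewed
along the co-oriented plane normal (u × v = n for the in-plane basis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .columns import ColumnPath
from .errors import DegenerateGeometryError

DEFAULT_LEVELS = np.round(np.linspace(0.0, 1.0, 21), 10)


def iso_percentile_points(paths: dict[str, ColumnPath], t: float) -> dict[str, np.ndarray]:
    """Arc-length point at depth fraction t for every column spanning t."""
    points = {
        animal: path.point_at_depth(t) for animal, path in paths.items() if path.is_unit
    }
    if not points:
        raise DegenerateGeometryError(f"no columns span depth {t:g}")
    return points


def best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total-least-squares plane through ≥ 3 non-collinear points.

    Returns (origin, basis, normal): origin is the centroid, the normal is
    the smallest-variance principal direction, and the (2, 3) basis holds
    the two remaining principal directions.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 3:
        raise DegenerateGeometryError("need at least 3 points in 3D")
    origin = points.mean(axis=0)
    centered = points - origin
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < max(1e-12, 1e-9 * svals[0]):
        raise DegenerateGeometryError("points are collinear; plane undefined")
    return origin, vt[:2], vt[2]


@dataclass
class PercentileMap:
    """2D configuration of columns at one unit depth.

    ``points3d`` are the iso-percentile 3D points (µm); ``coords`` their
    orthogonal projections onto the plane spanned by ``basis`` at
    ``origin``.  Both are ordered like ``animal_ids``.
    """

    depth: float
    origin: np.ndarray
    basis: np.ndarray  # (2, 3), rows orthonormal, u × v = normal
    normal: np.ndarray  # (3,)
    animal_ids: list[str]
    points3d: np.ndarray  # (n, 3)
    coords: np.ndarray  # (n, 2)

    def coords_for(self, ids: list[str]) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.animal_ids)}
        return self.coords[[index[a] for a in ids]]


def _project(points3d: np.ndarray, origin: np.ndarray, basis: np.ndarray) -> np.ndarray:
    return (points3d - origin) @ basis.T


def make_percentile_map(points_by_id: dict[str, np.ndarray], depth: float) -> PercentileMap:
    ids = sorted(points_by_id)
    pts = np.array([points_by_id[a] for a in ids], dtype=float)
    origin, basis, normal = best_fit_plane(pts)
    # enforce right-handed basis so rotations are CCW about the normal
    if np.dot(np.cross(basis[0], basis[1]), normal) < 0:
        basis = np.array([basis[0], -basis[1]])
    return PercentileMap(
        depth=float(depth),
        origin=origin,
        basis=basis,
        normal=normal,
        animal_ids=ids,
        points3d=pts,
        coords=_project(pts, origin, basis),
    )


def build_map_stack(
    paths: dict[str, ColumnPath], levels: np.ndarray | None = None
) -> list[PercentileMap]:
    """Percentile maps at every depth level (default 0 … 1, step 0.05)."""
    if levels is None:
        levels = DEFAULT_LEVELS
    return [make_percentile_map(iso_percentile_points(paths, t), t) for t in levels]


def orient_stack(
    maps: list[PercentileMap], reference_direction: np.ndarray
) -> list[PercentileMap]:
    """Co-orient normals and chain the in-plane bases through the stack.

    Plane normals from the SVD carry an arbitrary sign and the in-plane
    bases an arbitrary rotation, which would confound the rotation between
    neighbouring maps.  Normals are flipped to point along the mean
    pial→ventral direction, and each map's u axis is the previous map's u
    axis projected into the current plane (the minimal in-plane rotation),
    with v = n × u.  Relative geometry of the column points is unchanged.
    """
    reference_direction = np.asarray(reference_direction, dtype=float)
    oriented: list[PercentileMap] = []
    prev_u: np.ndarray | None = None
    for m in maps:
        n = m.normal if np.dot(m.normal, reference_direction) >= 0 else -m.normal
        if prev_u is None:
            u = m.basis[0]
            u = u - np.dot(u, n) * n
        else:
            u = prev_u - np.dot(prev_u, n) * n
            if np.linalg.norm(u) < 1e-9:  # pathological: plane ⟂ previous u
                u = m.basis[0] - np.dot(m.basis[0], n) * n
        u = u / np.linalg.norm(u)
        v = np.cross(n, u)
        basis = np.vstack([u, v])
        oriented.append(
            PercentileMap(
                depth=m.depth,
                origin=m.origin,
                basis=basis,
                normal=n,
                animal_ids=list(m.animal_ids),
                points3d=m.points3d,
                coords=_project(m.points3d, m.origin, basis),
            )
        )
        prev_u = u
    return oriented


# ---------------------------------------------------------------------------
# similarity alignment


@dataclass
class AlignmentStep:
    """Similarity transform b ≈ E·R(θ)·a + translation between two maps."""

    expansion: float
    rotation_rad: float
    translation_um: np.ndarray
    residual_um2: float  # mean squared distance after alignment
    n_shared: int


def similarity_procrustes(a: np.ndarray, b: np.ndarray):
    """Closed-form least-squares similarity (rotation + scale, no reflection).

    Returns (E, θ, translation, residual).  Uses the complex-plane
    formulation: with centred points â, b̂ the optimum is
    E·e^{iθ} = Σ conj(â)·b̂ / Σ |â|².
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2 or len(a) < 2:
        raise DegenerateGeometryError("need matched (n, 2) arrays with n ≥ 2")
    ca = a - a.mean(axis=0)
    cb = b - b.mean(axis=0)
    za = ca[:, 0] + 1j * ca[:, 1]
    zb = cb[:, 0] + 1j * cb[:, 1]
    denom = (np.abs(za) ** 2).sum()
    if denom < 1e-18:
        raise DegenerateGeometryError("all points of map a coincident")
    s = (np.conj(za) * zb).sum() / denom
    E = float(np.abs(s))
    theta = float(np.angle(s))
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    translation = b.mean(axis=0) - E * (R @ a.mean(axis=0))
    resid = float(np.mean(np.sum((E * a @ R.T + translation - b) ** 2, axis=1)))
    return E, theta, translation, resid


def _wrap_angle(theta: float) -> float:
    wrapped = (theta + np.pi) % (2 * np.pi) - np.pi
    return np.pi if np.isclose(wrapped, -np.pi) else wrapped


def constrained_similarity(
    a: np.ndarray,
    b: np.ndarray,
    expansion_bounds: tuple[float, float] = (0.1, 10.0),
) -> AlignmentStep:
    """Bounded minimisation of the mean squared alignment distance.

    Starts from the closed-form Procrustes solution and refines with
    L-BFGS-B under E ∈ [0.1, 10] and θ ∈ (−π, π]; on interior optima the
    two agree to solver tolerance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    E0, th0, tr0, _ = similarity_procrustes(a, b)
    lo, hi = expansion_bounds
    x0 = np.array([np.clip(E0, lo, hi), _wrap_angle(th0), tr0[0], tr0[1]])

    def objective(x):
        E, th, tx, ty = x
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        d = E * a @ R.T + np.array([tx, ty]) - b
        return np.mean(np.sum(d * d, axis=1))

    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[(lo, hi), (-np.pi, np.pi), (None, None), (None, None)],
        options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
    )
    E, th, tx, ty = res.x
    return AlignmentStep(
        expansion=float(E),
        rotation_rad=float(_wrap_angle(th)),
        translation_um=np.array([tx, ty]),
        residual_um2=float(res.fun),
        n_shared=len(a),
    )


def align_maps(map_a, map_b) -> AlignmentStep:
    """Align two percentile maps on their shared columns.

    Accepts :class:`PercentileMap` objects (matched by animal_id; columns
    absent from either map are dropped pairwise) or plain matched (n, 2)
    arrays.
    """
    if isinstance(map_a, PercentileMap) and isinstance(map_b, PercentileMap):
        shared = sorted(set(map_a.animal_ids) & set(map_b.animal_ids))
        if len(shared) < 2:
            raise DegenerateGeometryError(
                f"maps share only {len(shared)} columns; need at least 2"
            )
        a = map_a.coords_for(shared)
        b = map_b.coords_for(shared)
    else:
        a, b = np.asarray(map_a, dtype=float), np.asarray(map_b, dtype=float)
    return constrained_similarity(a, b)


@dataclass
class TrajectorySummary:
    """Cumulative rotation/expansion of the map stack vs the pial plane."""

    depths: np.ndarray  # (n_steps + 1,)
    cumulative_rotation_rad: np.ndarray  # anchored at 0
    cumulative_expansion: np.ndarray  # anchored at 1


def cumulative_trajectory(
    steps: list[AlignmentStep], depths: np.ndarray | None = None
) -> TrajectorySummary:
    """Sum rotations and multiply expansions depth by depth."""
    if depths is None:
        depths = np.linspace(0.0, 1.0, len(steps) + 1)
    rot = np.concatenate([[0.0], np.cumsum([s.rotation_rad for s in steps])])
    exp = np.concatenate([[1.0], np.cumprod([s.expansion for s in steps])])
    return TrajectorySummary(
        depths=np.asarray(depths, dtype=float),
        cumulative_rotation_rad=rot,
        cumulative_expansion=exp,
    )


def align_stack(maps: list[PercentileMap]) -> list[AlignmentStep]:
    """Alignment steps between each consecutive pair of oriented maps."""
    return [align_maps(maps[i - 1], maps[i]) for i in range(1, len(maps))]
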