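"""Column trajectory fitting and unit-column depth profiles.

A projection column is the 3D cloud of retrogradely labelled somata from
one V1 injection.  Its trajectory is summarised by a quadratic piecewise
polynomial (5 break parameters including the endpoints, i.e. four C1
pieces) fitted per axis against an ordering parameter.  The trajectory is
extrapolated along its terminal tangents to the nucleus surface; the end
crossing a pial-labelled face defines depth 0 and the opposite (ventral)
crossing depth 1.  Each cell then gets a unit depth t (arc-length fraction
of its nearest trajectory point) and a radial spread r (perpendicular
distance to the trajectory, µm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import trimesh
from scipy.interpolate import BSpline, make_lsq_spline

from ._geometry import contains, ray_intersections
from .core import NucleusMesh
from .errors import (
    AmbiguousBoundaryError,
    DegenerateGeometryError,
    NoIntersectionError,
)

N_BREAKS = 5  # break parameters including both endpoints -> 3 interior knots
SPLINE_DEGREE = 2
MIN_CELLS = 10
_DENSE = 512  # samples used to discretise a trajectory


@dataclass
class ColumnPath:
    """Fitted column trajectory.

    ``spline`` maps the fit parameter s ∈ [0, 1] to 3D µm coordinates; the
    parameter orientation is arbitrary until the boundary intersection
    determines which end is pial.  After :func:`clip_to_boundary` the
    ``polyline``/``arclength_um`` fields describe the unit column running
    pial → ventral and ``total_length_um`` is its arc length.
    """

    spline: BSpline
    breaks: np.ndarray
    animal_id: str = ""
    pial_point: np.ndarray | None = None
    ventral_point: np.ndarray | None = None
    polyline: np.ndarray | None = None
    arclength_um: np.ndarray | None = None
    total_length_um: float | None = None

    def __call__(self, s) -> np.ndarray:
        return self.spline(np.asarray(s, dtype=float))

    def tangent(self, s) -> np.ndarray:
        d = self.spline.derivative()(np.asarray(s, dtype=float))
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    @property
    def is_unit(self) -> bool:
        return self.polyline is not None

    def point_at_depth(self, t: float) -> np.ndarray:
        """Arc-length point at unit depth t ∈ [0, 1] (0 = pial)."""
        if not self.is_unit:
            raise DegenerateGeometryError("path has no boundary intersections yet")
        s = float(t) * self.total_length_um
        out = np.empty(3)
        for axis in range(3):
            out[axis] = np.interp(s, self.arclength_um, self.polyline[:, axis])
        return out


def _rank_parameter(order_values: np.ndarray) -> np.ndarray:
    """Uniform [0, 1] parameter from the rank order of a 1D projection."""
    n = len(order_values)
    ranks = np.empty(n)
    ranks[np.argsort(order_values, kind="stable")] = np.arange(n)
    return ranks / (n - 1)


def _fit_axes(s: np.ndarray, points: np.ndarray) -> BSpline:
    order = np.argsort(s, kind="stable")
    x = s[order]
    # make_lsq_spline needs strictly increasing abscissae
    x = x + np.arange(len(x)) * 1e-12
    interior = np.linspace(0.0, 1.0, N_BREAKS)[1:-1]
    knots = np.concatenate(
        [np.repeat(x[0], SPLINE_DEGREE + 1), interior, np.repeat(x[-1], SPLINE_DEGREE + 1)]
    )
    return make_lsq_spline(x, points[order], knots, k=SPLINE_DEGREE)


def fit_column_path(points: np.ndarray, animal_id: str = "") -> ColumnPath:
    """Fit the quadratic piecewise-polynomial trajectory of a cell cloud.

    The ordering parameter is the rank of each cell's projection onto the
    cloud's first principal axis, refined once by re-projecting the cells
    onto the fitted curve and re-ranking.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise DegenerateGeometryError("expected an (n, 3) point array")
    n = len(points)
    if n < MIN_CELLS:
        raise DegenerateGeometryError(f"need at least {MIN_CELLS} cells, got {n}")
    centered = points - points.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[0] < 1e-9:
        raise DegenerateGeometryError("all cells coincident")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    s0 = _rank_parameter(centered @ vt[0])
    try:
        spline = _fit_axes(s0, points)
        # one fixed refinement: re-order by position along the fitted curve
        s_dense = np.linspace(0.0, 1.0, _DENSE)
        curve = spline(s_dense)
        d2 = ((points[:, None, :] - curve[None, :, :]) ** 2).sum(axis=2)
        s1 = _rank_parameter(s_dense[np.argmin(d2, axis=1)] + 1e-9 * s0)
        spline = _fit_axes(s1, points)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise DegenerateGeometryError(f"rank-deficient spline system: {exc}") from None
    breaks = np.linspace(0.0, 1.0, N_BREAKS)
    return ColumnPath(spline=spline, breaks=breaks, animal_id=animal_id)


# ---------------------------------------------------------------------------
# boundary intersection


def _spline_length(path: ColumnPath) -> float:
    pts = path(np.linspace(0.0, 1.0, _DENSE))
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _end_crossing(path: ColumnPath, mesh: NucleusMesh, end: float, max_extension: float):
    """Surface crossing associated with one path end.

    Returns (point, face_index, s_clip).  A path end already on the surface
    (within 1e-6 µm) is returned unchanged; an end inside the mesh is
    extended outward along its terminal tangent to the first crossing
    (s_clip stays at the end); an end that overshot the surface is walked
    back along the curve to where the curve itself crosses (s_clip is the
    spline parameter of the first interior sample).
    """
    point = path(end)
    tangent = path.tangent(end)
    outward = -tangent if end == 0.0 else tangent
    closest, dist, face = trimesh.proximity.closest_point_naive(mesh.trimesh, point[None, :])
    if dist[0] < 1e-6:
        return point, int(face[0]), end
    if contains(mesh.vertices, mesh.faces, point[None, :])[0]:
        distances, hit_faces, locations = ray_intersections(
            mesh.vertices, mesh.faces, point, outward
        )
        if len(distances) == 0:
            raise NoIntersectionError(
                f"path end at s={end:g} never crosses the mesh along its tangent"
            )
        if distances[0] > max_extension:
            # a noisy terminal tangent can run almost parallel to a nearby
            # surface; for an end that is demonstrably close to the
            # boundary, its nearest surface point is the robust crossing
            if dist[0] < 0.1 * max_extension:
                return np.asarray(closest[0]), int(face[0]), end
            raise NoIntersectionError(
                f"nearest crossing {distances[0]:.1f} µm exceeds the maximum "
                f"extension {max_extension:.1f} µm"
            )
        return locations[0], int(hit_faces[0]), end
    # end overshot the surface: find where the curve itself crosses
    s_grid = np.linspace(end, 1.0 - end, _DENSE)
    samples = path(s_grid)
    inside = contains(mesh.vertices, mesh.faces, samples)
    if not inside.any():
        raise NoIntersectionError("fitted path lies entirely outside the mesh")
    first_in = int(np.argmax(inside))
    if first_in == 0:  # numerically on the surface already
        return samples[0], int(face[0]), end
    origin = samples[first_in]
    direction = samples[first_in - 1] - origin
    distances, hit_faces, locations = ray_intersections(
        mesh.vertices, mesh.faces, origin, direction
    )
    if len(distances) == 0:  # grazing configuration; fall back to nearest point
        return np.asarray(closest[0]), int(face[0]), float(s_grid[first_in])
    return locations[0], int(hit_faces[0]), float(s_grid[first_in])


def intersect_boundary(
    path: ColumnPath, mesh: NucleusMesh, max_extension_um: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Extend both path ends to the nucleus surface; identify the pial end.

    Each end is extended along its terminal tangent until the first mesh
    crossing (at most one path length away by default).  The end whose
    crossing lies on a pial-labelled face is the pial point; exactly one
    end must do so.
    """
    (p_pial, _), (p_vent, _) = _oriented_crossings(path, mesh, max_extension_um)
    return p_pial, p_vent


def _oriented_crossings(path, mesh, max_extension_um):
    if max_extension_um is None:
        max_extension_um = _spline_length(path)
    p_start, f_start, s_start = _end_crossing(path, mesh, 0.0, max_extension_um)
    p_end, f_end, s_end = _end_crossing(path, mesh, 1.0, max_extension_um)
    start_pial = mesh.is_pial_face(f_start)
    end_pial = mesh.is_pial_face(f_end)
    if start_pial and end_pial:
        raise AmbiguousBoundaryError("both path ends cross pial-labelled faces")
    if not start_pial and not end_pial:
        raise AmbiguousBoundaryError("neither path end crosses a pial-labelled face")
    if start_pial:
        return (p_start, s_start), (p_end, s_end)
    return (p_end, s_end), (p_start, s_start)


def clip_to_boundary(
    path: ColumnPath, mesh: NucleusMesh, max_extension_um: float | None = None
) -> ColumnPath:
    """Return the path completed with pial/ventral points and unit polyline.

    The polyline runs pial → ventral: spline samples between the two clip
    parameters, with straight terminal extensions to any crossing that lies
    beyond a spline end.
    """
    (pial, s_pial), (ventral, s_vent) = _oriented_crossings(path, mesh, max_extension_um)
    lo, hi = sorted([s_pial, s_vent])
    samples = path(np.linspace(lo, hi, _DENSE))
    if np.linalg.norm(samples[0] - pial) > np.linalg.norm(samples[-1] - pial):
        samples = samples[::-1]
    polyline = np.vstack([pial, samples, ventral])
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    polyline = polyline[keep]
    arclen = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(polyline, axis=0), axis=1))])
    total = float(arclen[-1])
    if total <= 0:
        raise DegenerateGeometryError("zero-length unit column")
    return replace(
        path,
        pial_point=np.asarray(pial, dtype=float),
        ventral_point=np.asarray(ventral, dtype=float),
        polyline=polyline,
        arclength_um=arclen,
        total_length_um=total,
    )


def reconstruct_column(points: np.ndarray, mesh: NucleusMesh, animal_id: str = "") -> ColumnPath:
    """Fit, extrapolate and unit-parameterize one column in a single call."""
    return clip_to_boundary(fit_column_path(points, animal_id=animal_id), mesh)


# ---------------------------------------------------------------------------
# unit column


@dataclass
class UnitColumn:
    """Per-cell unit depth t ∈ [0, 1] (0 = pial) and radial spread r (µm).

    ``clipped`` flags cells whose perpendicular foot fell beyond a column
    end; their t is clamped to 0/1 and they are excluded from depth-binned
    profiles (but retained here so nothing is silently dropped).
    """

    t: np.ndarray
    r_um: np.ndarray
    clipped: np.ndarray
    animal_id: str = ""

    @property
    def n_cells(self) -> int:
        return len(self.t)

    @property
    def n_clipped(self) -> int:
        return int(self.clipped.sum())


def unitize(points: np.ndarray, path: ColumnPath) -> UnitColumn:
    """Project cells onto the unit column.

    t is the arc length of the nearest trajectory point from the pial end
    divided by the total length; r is the Euclidean distance from the cell
    to that nearest point.
    """
    if not path.is_unit:
        raise DegenerateGeometryError("path must be clipped to the boundary first")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    P = path.polyline
    A, B = P[:-1], P[1:]
    AB = B - A
    seg_len2 = (AB**2).sum(axis=1)
    # per-cell, per-segment projection parameter (unclamped)
    u_raw = ((points[:, None, :] - A[None, :, :]) * AB[None, :, :]).sum(axis=2) / seg_len2
    u = np.clip(u_raw, 0.0, 1.0)
    foot = A[None, :, :] + u[:, :, None] * AB[None, :, :]
    d2 = ((points[:, None, :] - foot) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    rows = np.arange(len(points))
    r = np.sqrt(d2[rows, best])
    arc = path.arclength_um[best] + u[rows, best] * np.sqrt(seg_len2[best])
    t = np.clip(arc / path.total_length_um, 0.0, 1.0)
    clipped = ((best == 0) & (u_raw[rows, 0] < 0.0)) | (
        (best == len(AB) - 1) & (u_raw[rows, -1] > 1.0)
    )
    return UnitColumn(t=t, r_um=r, clipped=clipped, animal_id=path.animal_id)


# ---------------------------------------------------------------------------
# depth profiles


@dataclass
class DepthProfile:
    """Across-column mean ± SEM of a per-bin value along the unit column."""

    edges: np.ndarray  # (n_bins + 1,)
    mean: np.ndarray  # (n_bins,)
    sem: np.ndarray  # (n_bins,)
    n_columns: int
    kind: str
    group: str = ""

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def bin_index(t: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Half-open depth bins of width 1/n_bins; t = 1 goes to the last bin."""
    return np.minimum((np.asarray(t) * n_bins).astype(int), n_bins - 1)


def _per_column_bins(col: UnitColumn, n_bins: int):
    keep = ~col.clipped
    return bin_index(col.t[keep], n_bins), col.r_um[keep]


def count_profile(unit_columns: list[UnitColumn], n_bins: int = 20, group: str = "") -> DepthProfile:
    """Mean ± SEM of per-bin cell counts across columns."""
    if not unit_columns:
        raise DegenerateGeometryError("no columns to profile")
    counts = np.zeros((len(unit_columns), n_bins))
    for i, col in enumerate(unit_columns):
        bins, _ = _per_column_bins(col, n_bins)
        np.add.at(counts[i], bins, 1.0)
    mean = counts.mean(axis=0)
    n = len(unit_columns)
    sem = counts.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(n_bins)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return DepthProfile(edges=edges, mean=mean, sem=sem, n_columns=n, kind="count", group=group)


def spread_profile(
    unit_columns: list[UnitColumn],
    volume_scale: float = 1.0,
    n_bins: int = 20,
    group: str = "",
) -> DepthProfile:
    """Mean ± SEM across columns of per-bin mean radial spread (µm).

    ``volume_scale`` rescales radii to a reference nucleus size; use
    (V_ref / V_group)^(1/3).
    """
    if volume_scale <= 0:
        raise DegenerateGeometryError("volume_scale must be positive")
    if not unit_columns:
        raise DegenerateGeometryError("no columns to profile")
    per_col = np.full((len(unit_columns), n_bins), np.nan)
    for i, col in enumerate(unit_columns):
        bins, radii = _per_column_bins(col, n_bins)
        for b in np.unique(bins):
            per_col[i, b] = radii[bins == b].mean() * volume_scale
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # bins no column occupies
        mean = np.nanmean(per_col, axis=0)
        n_per_bin = np.sum(~np.isnan(per_col), axis=0)
        sd = np.nanstd(per_col, axis=0, ddof=1)
    sem = np.where(n_per_bin > 1, sd / np.sqrt(np.maximum(n_per_bin, 1)), 0.0)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return DepthProfile(
        edges=edges,
        mean=mean,
        sem=sem,
        n_columns=len(unit_columns),
        kind="spread",
        group=group,
    )


# ---------------------------------------------------------------------------
# Rayleigh fit to radial spread


@dataclass
class RayleighFit:
    """Maximum-likelihood Rayleigh scale for radial spread distributions."""

    sigma_um: float
    n: int
    log_likelihood: float


def fit_rayleigh(radii_um) -> RayleighFit:
    """MLE of the Rayleigh scale: σ² = Σ r² / (2 n)."""
    r = np.asarray(radii_um, dtype=float)
    if r.ndim != 1 or len(r) < 2:
        raise DegenerateGeometryError("need at least 2 radii")
    if (r < 0).any():
        raise DegenerateGeometryError("radii must be non-negative")
    if not (r > 0).any():
        raise DegenerateGeometryError("all radii are zero; Rayleigh fit degenerate")
    n = len(r)
    sigma = float(np.sqrt((r**2).sum() / (2 * n)))
    with np.errstate(divide="ignore"):
        loglik = float(np.log(r).sum() - 2 * n * np.log(sigma) - (r**2).sum() / (2 * sigma**2))
    return RayleighFit(sigma_um=sigma, n=n, log_likelihood=loglik)
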