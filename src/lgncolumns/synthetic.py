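"""Synthetic nucleus, projection columns and profile matrices with ground truth.

The generator emulates the data model of the real experiment: an
ellipsoidal nucleus-like surface with a dorsal pial cap, curved column
trajectories that rotate and expand with depth, Poisson cell counts per
depth bin with Rayleigh-distributed radial scatter, a topographic V1 ↔
column correspondence with a controllable scrambling fraction, and
low-rank profile matrices for the latent scan.  Every generated quantity
is recorded in a :class:`GroundTruth` so recovery can be tested.

Default condition: 16 columns per group (matching the adult wild-type
animal count), 8 cells per 5%-depth bin (≈ 160 cells per column, the
order of magnitude of a focal tracer injection), Rayleigh radial scatter
σ = 25 µm, a 500 × 400 × 600 µm half-axis ellipsoid nucleus, a gentle
40 µm medio-lateral bend, and a prescribed linear rotation (0.5 rad total)
and expansion (×1.3 total) of the column array with depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import trimesh
from scipy.optimize import brentq

from .core import CellRecord, Dataset, Group, InjectionRecord, NucleusMesh, Tracer
from .errors import DegenerateGeometryError, LgnError
from .latents import ProfileMatrix, standardize_profile

N_BINS = 20
DEPTH_LEVELS = np.round(np.linspace(0.0, 1.0, 21), 10)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic group."""

    seed: int = 0
    group: Group = Group.WT
    n_columns: int = 16
    lambda_per_bin: np.ndarray = field(default_factory=lambda: np.full(N_BINS, 8.0))
    sigma_um: float = 25.0  # Rayleigh radial scatter scale (constant over depth)
    curvature_um: float = 40.0  # medio-lateral bend amplitude of the column array
    total_rotation_rad: float = 0.5  # θ*(t) = t · total
    total_expansion: float = 1.3  # E*(t) = 1 + t · (total − 1)
    scramble_fraction: float = 0.0  # ρ: fraction of injection↔column pairs permuted
    radii_um: tuple[float, float, float] = (500.0, 400.0, 600.0)
    cap_angle_deg: float = 55.0  # polar half-angle of the pial cap about +y
    mesh_subdivisions: int = 3
    column_spread_um: float = 120.0  # lateral half-extent of the column array
    injection_scale_mm_per_um: float = 0.004
    injection_center_mm: tuple[float, float] = (-0.5, 2.2)  # (ap, ml) rel. lambda

    def __post_init__(self):
        self.lambda_per_bin = np.asarray(self.lambda_per_bin, dtype=float)
        if (self.lambda_per_bin < 0).any():
            raise LgnError("per-bin rates must be non-negative")
        if not 0.0 <= self.scramble_fraction <= 1.0:
            raise LgnError("scramble_fraction must lie in [0, 1]")
        if min(self.radii_um) <= 0:
            raise DegenerateGeometryError("ellipsoid radii must be positive")
        if self.sigma_um < 0:
            raise LgnError("sigma_um must be non-negative")

    def rotation_at(self, t) -> np.ndarray:
        return self.total_rotation_rad * np.asarray(t, dtype=float)

    def expansion_at(self, t) -> np.ndarray:
        return 1.0 + (self.total_expansion - 1.0) * np.asarray(t, dtype=float)


@dataclass
class GroundTruth:
    """Everything the generator knows about what it produced."""

    true_t: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_r_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    cell_animal_ids: list[str] = field(default_factory=list)
    paths: dict[str, np.ndarray] = field(default_factory=dict)  # dense pial→ventral
    rotation_at_levels: np.ndarray | None = None
    expansion_at_levels: np.ndarray | None = None
    correspondence: dict[str, str] = field(default_factory=dict)  # injection→column
    scrambled_ids: list[str] = field(default_factory=list)
    latent_rank: int | None = None
    signal: np.ndarray | None = None  # pre-noise profile matrix


def make_mesh(config: SyntheticConfig) -> NucleusMesh:
    """Closed triangulated ellipsoid with a pial cap about the +y pole.

    Faces whose unit-sphere centroid polar angle from +y is below
    ``cap_angle_deg`` are labelled pial.  The icosphere tessellation keeps
    the enclosed volume within a fraction of a percent of 4πabc/3.
    """
    a, b, c = config.radii_um
    unit = trimesh.creation.icosphere(subdivisions=config.mesh_subdivisions, radius=1.0)
    vertices = unit.vertices * np.array([a, b, c])
    centroids = unit.vertices[unit.faces].mean(axis=1)
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    polar = np.degrees(np.arccos(np.clip(centroids[:, 1], -1.0, 1.0)))
    pial = np.nonzero(polar < config.cap_angle_deg)[0]
    return NucleusMesh(vertices, unit.faces, pial)


def _ellipsoid_value(point: np.ndarray, radii) -> float:
    a, b, c = radii
    return (point[0] / a) ** 2 + (point[1] / b) ** 2 + (point[2] / c) ** 2 - 1.0


def _column_curve(config: SyntheticConfig, offset: np.ndarray, tau_of_d):
    """Parametric column position over a depth parameter d (pial ≈ 0).

    The rotation/expansion/bend fields are evaluated at τ = ``tau_of_d(d)``,
    the column's own unit depth; see :func:`_build_column`.
    """
    b = config.radii_um[1]

    def position(d: np.ndarray) -> np.ndarray:
        d = np.atleast_1d(np.asarray(d, dtype=float))
        tau = np.clip(tau_of_d(d), 0.0, 1.0)
        theta = config.rotation_at(tau)
        e = config.expansion_at(tau)
        bend = config.curvature_um * np.sin(np.pi * tau)
        x = bend + e * (np.cos(theta) * offset[0] - np.sin(theta) * offset[1])
        z = e * (np.sin(theta) * offset[0] + np.cos(theta) * offset[1])
        y = b * (1.0 - 2.0 * d)
        return np.column_stack([x, y, z])

    return position


def _clip_to_ellipsoid(position, radii, n_dense: int = 801):
    """Clip a parametric curve to the ellipsoid; return (polyline, t_of_d).

    The curve is sampled on d ∈ [−0.3, 1.3]; the outer-to-inner crossings
    nearest each end are located by root finding and the clipped piece is
    re-parameterized by arc-length fraction t ∈ [0, 1] (top = pial = 0).
    """
    d_grid = np.linspace(-0.3, 1.3, n_dense)
    pts = position(d_grid)
    vals = np.array([_ellipsoid_value(p, radii) for p in pts])
    inside = vals < 0
    if not inside.any():
        raise DegenerateGeometryError("column never enters the nucleus")
    first, last = np.nonzero(inside)[0][[0, -1]]
    if first == 0 or last == n_dense - 1:
        raise DegenerateGeometryError("column does not exit the nucleus")

    def f(d):
        return _ellipsoid_value(position(d)[0], radii)

    d_top = brentq(f, d_grid[first - 1], d_grid[first])
    d_bot = brentq(f, d_grid[last], d_grid[last + 1])
    d_clip = np.linspace(d_top, d_bot, n_dense)
    poly = position(d_clip)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    t_of_d = arc / arc[-1]
    return poly, d_clip, t_of_d


def _build_column(config: SyntheticConfig, offset: np.ndarray, n_iter: int = 4):
    """Column whose fields are self-consistently functions of unit depth.

    The prescribed rotation θ*(t) and expansion E*(t) are meant as
    functions of the clipped column's own arc-length fraction t, but the
    clip depends on the curve and vice versa.  A short fixed-point
    iteration (re-expressing the field argument through the previous
    iterate's arc-length map) converges to milliradian consistency in a
    few rounds, so the recorded ground-truth fields hold exactly along
    each generated column.
    """

    def tau0(d):
        return np.clip(np.asarray(d, dtype=float), 0.0, 1.0)

    tau = tau0
    position = _column_curve(config, offset, tau)
    for _ in range(n_iter):
        poly, d_clip, t_of_d = _clip_to_ellipsoid(position, config.radii_um)

        def tau(d, dc=d_clip, tc=t_of_d):
            return np.interp(np.asarray(d, dtype=float), dc, tc)

        position = _column_curve(config, offset, tau)
    poly, d_clip, t_of_d = _clip_to_ellipsoid(position, config.radii_um)
    return position, poly, d_clip, t_of_d


def _frame_perpendicular(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tangent = tangent / np.linalg.norm(tangent)
    helper = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(helper, tangent)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(tangent, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(tangent, e1)
    return e1, e2


def _column_offsets(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic lateral grid of column entry offsets, lightly jittered."""
    n = config.n_columns
    side = ceil(np.sqrt(n))
    lin = np.linspace(-1.0, 1.0, side) if side > 1 else np.array([0.0])
    gx, gz = np.meshgrid(lin, lin, indexing="ij")
    grid = np.column_stack([gx.ravel(), gz.ravel()])[:n] * config.column_spread_um
    jitter = rng.uniform(-0.08, 0.08, grid.shape) * config.column_spread_um
    return grid + jitter


def scramble_injections(
    pairing: dict[str, str], fraction: float, rng: np.random.Generator
) -> tuple[dict[str, str], list[str]]:
    """Randomly re-pair a ⌈fraction·n⌉ subset of injection↔column matches."""
    ids = sorted(pairing)
    m = ceil(fraction * len(ids))
    if m < 2:
        return dict(pairing), []
    chosen = sorted(rng.choice(len(ids), size=m, replace=False))
    perm = rng.permutation(m)
    out = dict(pairing)
    for slot, src in zip(chosen, perm):
        out[ids[slot]] = pairing[ids[chosen[src]]]
    return out, [ids[i] for i in chosen]


def make_columns(
    config: SyntheticConfig, mesh: NucleusMesh | None = None
) -> tuple[Dataset, GroundTruth]:
    """Generate one group's dataset of labelled columns plus ground truth."""
    if mesh is None:
        mesh = make_mesh(config)
    streams = np.random.SeedSequence(config.seed).spawn(4)
    r_layout, r_cells, r_scramble, r_tracer = (np.random.default_rng(s) for s in streams)
    offsets = _column_offsets(config, r_layout)
    prefix = config.group.value.lower()
    bin_edges = np.linspace(0.0, 1.0, N_BINS + 1)

    cells: list[CellRecord] = []
    truth = GroundTruth(
        rotation_at_levels=config.rotation_at(DEPTH_LEVELS),
        expansion_at_levels=config.expansion_at(DEPTH_LEVELS),
    )
    true_t: list[float] = []
    true_r: list[float] = []
    entry_offsets: dict[str, np.ndarray] = {}

    for i, offset in enumerate(offsets):
        animal = f"{prefix}{i:02d}"
        position, poly, d_clip, t_of_d = _build_column(config, offset)
        truth.paths[animal] = poly
        entry_offsets[animal] = offset
        tracer = Tracer.red if r_tracer.random() < 0.5 else Tracer.green
        counts = r_cells.poisson(config.lambda_per_bin)
        for b, count in enumerate(counts):
            if count == 0:
                continue
            ts = r_cells.uniform(bin_edges[b], bin_edges[b + 1], size=count)
            ds = np.interp(ts, t_of_d, d_clip)
            radii = (
                r_cells.rayleigh(scale=config.sigma_um, size=count)
                if config.sigma_um > 0
                else np.zeros(count)
            )
            phis = r_cells.uniform(0.0, 2 * np.pi, size=count)
            for t_cell, d_cell, r_cell, phi in zip(ts, ds, radii, phis):
                on_path = position(d_cell)[0]
                tangent = (position(d_cell + 1e-4)[0] - position(d_cell - 1e-4)[0]) / 2e-4
                e1, e2 = _frame_perpendicular(tangent)
                pos = on_path + r_cell * (np.cos(phi) * e1 + np.sin(phi) * e2)
                cells.append(
                    CellRecord(animal, config.group, tracer, pos[0], pos[1], pos[2])
                )
                true_t.append(float(t_cell))
                true_r.append(float(r_cell))

    if not cells:
        raise LgnError("configured rates produced zero cells")
    truth.true_t = np.array(true_t)
    truth.true_r_um = np.array(true_r)
    truth.cell_animal_ids = [c.animal_id for c in cells]

    # injections: fixed affine image (rotation + scale + offset) of the
    # pial entry offsets, then the scrambled re-pairing
    ang = np.deg2rad(25.0)
    A = config.injection_scale_mm_per_um * np.array(
        [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
    )
    pairing = {a: a for a in entry_offsets}  # injection id -> column id
    pairing, truth.scrambled_ids = scramble_injections(
        pairing, config.scramble_fraction, r_scramble
    )
    truth.correspondence = pairing
    injections = []
    for animal in sorted(entry_offsets):
        source_column = pairing[animal]
        ap, ml = A @ entry_offsets[source_column] + np.array(config.injection_center_mm)
        injections.append(InjectionRecord(animal, float(ap), float(ml)))

    dataset = Dataset(cells=cells, injections=injections, mesh=mesh, group=config.group)
    return dataset, truth


# ---------------------------------------------------------------------------
# low-rank profile matrices for the latent scan


def make_profile_matrix(
    rank: int,
    noise_sd: float,
    seed: int | None = None,
    n_rows: int = 16,
    n_levels: int = 21,
) -> tuple[ProfileMatrix, GroundTruth]:
    """Random smooth rank-k profile matrix plus relative Gaussian noise.

    Rows are random loadings on k smooth basis profiles (random invertible
    mixtures of the first k half-cosine harmonics on [0, 1]); noise SD is
    ``noise_sd`` times the signal SD; rows are standardized afterwards.
    """
    if rank < 1:
        raise LgnError(f"rank must be ≥ 1, got {rank}")
    if rank >= min(n_rows, n_levels):
        raise LgnError(f"rank must be < min(n_rows, n_levels) = {min(n_rows, n_levels)}")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_levels)
    harmonics = np.array([np.cos(np.pi * (h + 1) * t) for h in range(rank)])
    mix, _ = np.linalg.qr(rng.normal(size=(rank, rank)))
    basis = mix @ harmonics
    loadings = rng.normal(size=(n_rows, rank))
    signal = loadings @ basis
    noisy = signal + rng.normal(0.0, noise_sd * signal.std(), size=signal.shape)
    values = np.array([standardize_profile(row) for row in noisy])
    matrix = ProfileMatrix(
        values=values,
        metrics=[f"synthetic{i:02d}" for i in range(n_rows)],
        groups=["synthetic"] * n_rows,
        depths=t,
    )
    return matrix, GroundTruth(latent_rank=rank, signal=signal)
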