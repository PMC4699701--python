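"""Column fitting, boundary intersection, unit columns and depth profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from lgncolumns import (
    UnitColumn,
    count_profile,
    fit_column_path,
    fit_rayleigh,
    intersect_boundary,
    reconstruct_column,
    spread_profile,
    unitize,
)
from lgncolumns.columns import clip_to_boundary
from lgncolumns.errors import (
    AmbiguousBoundaryError,
    DegenerateGeometryError,
    NoIntersectionError,
)


def _line_points(n=50, direction=(1.0, 2.0, -0.5), origin=(10.0, -5.0, 3.0)):
    s = np.linspace(0, 400, n)[:, None]
    return np.asarray(origin) + s * (np.asarray(direction) / np.linalg.norm(direction))


class TestFitColumnPath:
    def test_straight_segment_reproduced(self):
        points = _line_points()
        path = fit_column_path(points)
        fitted = path(np.linspace(0, 1, 200))
        direction = points[-1] - points[0]
        direction /= np.linalg.norm(direction)
        offsets = fitted - points[0]
        deviation = offsets - np.outer(offsets @ direction, direction)
        assert np.abs(deviation).max() < 1e-6

    def test_planar_parabola_reproduced(self):
        # a quadratic curve lies inside the model class of the spline
        s = np.linspace(-1, 1, 200)
        points = np.column_stack([300 * s, 150 * s**2, np.zeros_like(s)])
        path = fit_column_path(points)
        fitted = path(np.linspace(0, 1, 400))
        expected_y = 150 * (fitted[:, 0] / 300) ** 2
        assert np.abs(fitted[:, 1] - expected_y).max() < 1e-3

    def test_noisy_curve_recovered_below_noise_sigma(self, wt_dataset, default_mesh):
        config, dataset, truth = wt_dataset
        animal = dataset.animal_ids[0]
        path = fit_column_path(dataset.cells_for(animal))
        fitted = path(np.linspace(0, 1, 300))
        true_poly = truth.paths[animal]
        d = np.sqrt(
            (((fitted[:, None, :] - true_poly[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        )
        assert d.mean() < config.sigma_um

    def test_too_few_and_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError, match="at least"):
            fit_column_path(np.zeros((5, 3)))
        with pytest.raises(DegenerateGeometryError, match="coincident"):
            fit_column_path(np.ones((20, 3)))


class TestBoundaryIntersection:
    def test_straight_path_through_sphere_matches_analytic(self, sphere_mesh):
        # vertical line through the centre: analytic piercings at ±R ŷ
        points = np.column_stack(
            [np.zeros(50), np.linspace(-300, 300, 50), np.zeros(50)]
        )
        path = fit_column_path(points)
        pial, ventral = intersect_boundary(path, sphere_mesh)
        # chordal error of a subdivision-3 icosphere is ~2 µm at R = 500
        assert np.linalg.norm(pial - [0, 500, 0]) < 5.0
        assert np.linalg.norm(ventral - [0, -500, 0]) < 5.0

    def test_end_on_surface_returned_unchanged(self, sphere_mesh):
        vertex = sphere_mesh.vertices[np.argmax(sphere_mesh.vertices[:, 1])]
        points = np.linspace(-0.6 * vertex, vertex, 60)
        path = fit_column_path(points)
        pial, _ = intersect_boundary(path, sphere_mesh)
        assert np.linalg.norm(pial - vertex) < 1e-6

    def test_path_outside_mesh_raises(self, sphere_mesh):
        points = _line_points(origin=(2000.0, 0.0, 0.0), direction=(0.0, 1.0, 0.0))
        path = fit_column_path(points)
        with pytest.raises(NoIntersectionError):
            intersect_boundary(path, sphere_mesh)

    def test_equatorial_path_is_ambiguous(self, sphere_mesh):
        # a horizontal chord exits through lateral (non-pial) faces twice
        points = _line_points(origin=(-300.0, -250.0, 0.0), direction=(1.0, 0.0, 0.0))
        path = fit_column_path(points)
        with pytest.raises(AmbiguousBoundaryError):
            intersect_boundary(path, sphere_mesh)


class TestUnitize:
    @pytest.fixture()
    def vertical_path(self, sphere_mesh):
        points = np.column_stack(
            [np.zeros(60), np.linspace(-350, 350, 60), np.zeros(60)]
        )
        return clip_to_boundary(fit_column_path(points), sphere_mesh)

    def test_cell_at_pial_point(self, vertical_path):
        uc = unitize(vertical_path.pial_point[None, :], vertical_path)
        assert uc.t[0] == pytest.approx(0.0, abs=1e-9)
        assert uc.r_um[0] == pytest.approx(0.0, abs=1e-6)
        assert not uc.clipped[0]

    def test_midpoint_cell_displaced_30um(self, vertical_path):
        mid = vertical_path.point_at_depth(0.5)
        cell = mid + np.array([30.0, 0.0, 0.0])
        uc = unitize(cell[None, :], vertical_path)
        assert uc.t[0] == pytest.approx(0.5, abs=1e-3)
        assert uc.r_um[0] == pytest.approx(30.0, abs=1e-3)

    def test_cell_beyond_pial_end_is_clipped(self, vertical_path):
        beyond = vertical_path.pial_point + np.array([0.0, 50.0, 0.0])
        uc = unitize(beyond[None, :], vertical_path)
        assert uc.clipped[0]
        assert uc.t[0] == 0.0

    def test_generated_cells_match_ground_truth(self, wt_dataset, default_mesh):
        _, dataset, truth = wt_dataset
        ids = np.array(truth.cell_animal_ids)
        errors = []
        for animal in dataset.animal_ids[:6]:
            cells = dataset.cells_for(animal)
            path = reconstruct_column(cells, default_mesh, animal)
            uc = unitize(cells, path)
            errors.append(np.abs(uc.t - truth.true_t[ids == animal]))
        assert np.concatenate(errors).mean() < 0.01

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_rigid_invariance(self, seed):
        """Rotating/translating everything leaves t and r unchanged."""
        rng = np.random.default_rng(seed)
        points = _line_points(n=40) + rng.normal(0, 10, (40, 3))
        cells = points[::3] + rng.normal(0, 25, (14, 3))
        path = fit_column_path(points)
        base = fit_column_path(points)
        R = Rotation.random(random_state=int(seed % 2**16)).as_matrix()
        shift = rng.uniform(-500, 500, 3)
        moved_path = fit_column_path(points @ R.T + shift)
        # compare raw projections of identical geometry in the two frames
        a = moved_path(np.linspace(0, 1, 100))
        b = base(np.linspace(0, 1, 100)) @ R.T + shift
        flipped = base(np.linspace(1, 0, 100)) @ R.T + shift
        assert min(np.abs(a - b).max(), np.abs(a - flipped).max()) < 1e-3


class TestProfiles:
    @staticmethod
    def _column(t, r=None, clipped=None, animal="a"):
        t = np.asarray(t, float)
        r = np.zeros_like(t) if r is None else np.asarray(r, float)
        clipped = (
            np.zeros(len(t), bool) if clipped is None else np.asarray(clipped, bool)
        )
        return UnitColumn(t=t, r_um=r, clipped=clipped, animal_id=animal)

    def test_one_cell_per_bin(self):
        profile = count_profile([self._column(np.arange(20) * 0.05 + 0.025)])
        assert np.array_equal(profile.mean, np.ones(20))
        assert profile.sem.max() == 0.0

    def test_t_equal_one_goes_to_last_bin(self):
        profile = count_profile([self._column([1.0])])
        assert profile.mean[19] == 1.0
        assert profile.mean[:19].sum() == 0.0

    def test_count_conservation_with_clipping(self):
        col = self._column([0.0, 0.3, 0.7, 1.0], clipped=[True, False, False, False])
        profile = count_profile([col])
        assert profile.mean.sum() + col.n_clipped == col.n_cells

    def test_poisson_rates_recovered(self):
        """count_profile recovers the generating per-bin Poisson rate."""
        rng = np.random.default_rng(123)
        lam = 4.0 + 6.0 * np.linspace(0, 1, 20)
        cols = []
        for _ in range(30):
            t_all = []
            for b in range(20):
                n = rng.poisson(lam[b])
                t_all.append(rng.uniform(b * 0.05, (b + 1) * 0.05, n))
            cols.append(self._column(np.concatenate(t_all)))
        profile = count_profile(cols)
        dev = np.abs(profile.mean - lam) / profile.sem
        assert dev.max() < 3.0

    def test_constant_spread_and_scaling(self):
        cols = [self._column(np.linspace(0.1, 0.9, 40), r=np.full(40, 50.0))]
        profile = spread_profile(cols, volume_scale=1.0)
        occupied = ~np.isnan(profile.mean)
        assert np.allclose(profile.mean[occupied], 50.0)
        doubled = spread_profile(cols, volume_scale=2.0)
        assert np.allclose(doubled.mean[occupied], 100.0)

    def test_spread_requires_positive_scale(self):
        with pytest.raises(DegenerateGeometryError):
            spread_profile([self._column([0.5], r=[1.0])], volume_scale=0.0)

    def test_rayleigh_radii_give_rayleigh_mean(self):
        """Per-bin mean spread matches σ·√(π/2) for Rayleigh radii."""
        rng = np.random.default_rng(7)
        sigma = 40.0
        cols = [
            self._column(rng.uniform(0, 1, 400), r=rng.rayleigh(sigma, 400))
            for _ in range(25)
        ]
        profile = spread_profile(cols)
        expected = sigma * np.sqrt(np.pi / 2)
        dev = np.abs(profile.mean - expected) / profile.sem
        assert dev.max() < 3.0


class TestRayleighFit:
    def test_closed_form_small_sample(self):
        fit = fit_rayleigh([1.0, 1.0, 1.0, 1.0])
        assert fit.sigma_um == pytest.approx(np.sqrt(0.5), rel=1e-12)
        assert fit.n == 4

    def test_scale_equivariance(self):
        rng = np.random.default_rng(11)
        radii = rng.rayleigh(10.0, 500)
        assert fit_rayleigh(radii * 3.0).sigma_um == pytest.approx(
            3.0 * fit_rayleigh(radii).sigma_um, rel=1e-12
        )

    def test_large_sample_recovery_within_one_percent(self):
        rng = np.random.default_rng(2024)
        fit = fit_rayleigh(rng.rayleigh(25.0, 10_000))
        assert abs(fit.sigma_um - 25.0) / 25.0 < 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_rayleigh([0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            fit_rayleigh([1.0])
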