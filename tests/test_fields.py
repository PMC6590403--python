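import numpy as np
import pytest

from vfareg.core import AttributedPointCloud, GaussianEnergyParams, RigidTransform, apply_transform
from vfareg.errors import DegenerateNeighborhoodError
from vfareg.fields import (
    analyze_force_field,
    curl_field,
    find_vortex,
    hooke_energy,
    potential,
    potential_gradient,
    total_energy,
)
from vfareg.matching import closest_points
from vfareg.synthetic import displace


class TestPotential:
    def test_zero_at_alignment(self):
        assert potential(0.0, 10.0) == 0.0

    def test_saturates_to_one(self):
        assert potential(1e6, 10.0) == pytest.approx(1.0, abs=1e-15)

    def test_value_at_one_aperture(self):
        assert potential(10.0, 10.0) == pytest.approx(1.0 - np.exp(-1.0), abs=1e-12)
        assert potential(10.0, 10.0) == pytest.approx(0.632121, abs=1e-6)

    def test_strictly_increasing(self):
        d = np.linspace(0, 50, 200)
        u = potential(d, 10.0)
        assert np.all(np.diff(u) > 0)
        assert np.all((u >= 0) & (u < 1))


class TestEnergies:
    def test_hooke_small_cases(self, small_phantom):
        from vfareg.matching import Correspondence

        corr = closest_points(small_phantom, small_phantom)
        assert hooke_energy(corr) == 0.0
        two = Correspondence([0, 1], [0, 1], [3.0, 4.0], [1, 1])
        assert hooke_energy(two) == pytest.approx(25.0)

    def test_hooke_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        from .conftest import random_cloud

        moving, fixed = random_cloud(rng, 80, 2), random_cloud(rng, 80, 2)
        corr = closest_points(moving, fixed)
        naive = sum(float(d) ** 2 for d in corr.distance_mm)
        assert hooke_energy(corr) == pytest.approx(naive, rel=1e-12)

    def test_total_energy_zero_iff_aligned(self, small_phantom):
        params = GaussianEnergyParams()
        corr = closest_points(small_phantom, small_phantom, params)
        assert total_energy(corr, params) == 0.0
        moved = apply_transform(small_phantom, RigidTransform([0, 0, 0], [1, 0, 0]))
        corr2 = closest_points(moved, small_phantom, params)
        assert total_energy(corr2, params) > 0.0

    def test_total_energy_saturates_at_n(self, small_phantom):
        params = GaussianEnergyParams()
        far = apply_transform(small_phantom, RigidTransform([0, 0, 0], [1e5, 0, 0]))
        corr = closest_points(far, small_phantom, params)
        n = small_phantom.n_attributed
        e = total_energy(corr, params)
        assert e == pytest.approx(n, abs=1e-9)
        assert e <= n

    def test_small_displacement_taylor_regime(self, small_phantom):
        """E_sigma ~ sum d^2 / sigma^2 within 1% when all d <= 0.1 sigma."""
        params = GaussianEnergyParams()
        moved = apply_transform(small_phantom,
                                RigidTransform([0, 0, 0], [0.5, 0.5, 0.5]))
        corr = closest_points(moved, small_phantom, params)
        assert corr.distance_mm.max() <= 0.1 * params.sigma
        quad = np.sum(corr.distance_mm**2) / params.sigma**2
        assert total_energy(corr, params) == pytest.approx(quad, rel=0.01)

    def test_energy_invariant_under_joint_rigid_motion(self, small_phantom):
        params = GaussianEnergyParams()
        moved = apply_transform(small_phantom, RigidTransform([10, 5, -3], [4, 1, 2]))
        e0 = total_energy(closest_points(moved, small_phantom, params), params)
        joint = RigidTransform([33, -21, 75], [40, -10, 25], [7, 8, 9])
        e1 = total_energy(closest_points(apply_transform(moved, joint),
                                         apply_transform(small_phantom, joint),
                                         params), params)
        assert e1 == pytest.approx(e0, abs=1e-9)


class TestPotentialGradient:
    def test_zero_gradient_at_zero_distance(self, small_phantom):
        params = GaussianEnergyParams()
        corr = closest_points(small_phantom, small_phantom, params)
        fs = potential_gradient(small_phantom, small_phantom, corr, params)
        assert np.all(fs.gradient == 0.0)
        np.testing.assert_array_equal(fs.force, -fs.gradient)

    def test_closed_form_single_point(self):
        fixed = AttributedPointCloud([[0, 0, 0]], [1])
        moving = AttributedPointCloud([[10, 0, 0]], [1])
        params = GaussianEnergyParams(sigma=10.0)
        corr = closest_points(moving, fixed, params)
        fs = potential_gradient(moving, fixed, corr, params)
        expected = (2.0 / 10.0) * np.exp(-1.0)
        np.testing.assert_allclose(fs.gradient[0], [expected, 0, 0], rtol=1e-12)
        np.testing.assert_allclose(fs.force[0], [-expected, 0, 0], rtol=1e-12)
        assert fs.gradient[0, 0] == pytest.approx(0.073576, abs=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_central_finite_differences(self, seed):
        """Analytic gradient of U_n vs central differences at random configurations."""
        rng = np.random.default_rng(seed)
        fixed = AttributedPointCloud(rng.normal(size=(30, 3)) * 30, np.full(30, 1))
        q = rng.normal(size=3) * 30
        moving = AttributedPointCloud(q[None, :], [1])
        params = GaussianEnergyParams(sigma=10.0)
        corr = closest_points(moving, fixed, params)
        fs = potential_gradient(moving, fixed, corr, params)
        h = 1e-4
        p_star = fixed.points[corr.fixed_index[0]]
        fd = np.zeros(3)
        for k in range(3):
            for sign in (1.0, -1.0):
                qq = q.copy()
                qq[k] += sign * h
                fd[k] += sign * potential(np.linalg.norm(qq - p_star), params.sigma)
        fd /= 2 * h
        np.testing.assert_allclose(fs.gradient[0], fd, rtol=1e-5, atol=1e-12)

    def test_forces_attract(self, small_phantom):
        """Moving each point a little along its force never increases its potential."""
        params = GaussianEnergyParams()
        moved = apply_transform(small_phantom, RigidTransform([8, -4, 12], [5, 2, -3]))
        corr = closest_points(moved, small_phantom, params)
        fs = potential_gradient(moved, small_phantom, corr, params)
        eps = 1e-4
        p_star = small_phantom.points[corr.fixed_index]
        u0 = potential(np.linalg.norm(fs.positions - p_star, axis=1), params.sigma)
        u1 = potential(np.linalg.norm(fs.positions + eps * fs.force - p_star, axis=1),
                       params.sigma)
        assert np.all(u1 <= u0 + 1e-15)


class TestCurl:
    def test_rotation_field(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(150, 3)) * 20
        forces = np.column_stack([-pts[:, 1], pts[:, 0], np.zeros(len(pts))])
        curl = curl_field(pts, forces, k_neighbors=12)
        np.testing.assert_allclose(curl, np.tile([0.0, 0.0, 2.0], (len(pts), 1)),
                                   atol=1e-10)

    def test_constant_field(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(100, 3)) * 10
        forces = np.tile([5.0, -1.0, 2.0], (100, 1))
        curl = curl_field(pts, forces, k_neighbors=8)
        np.testing.assert_allclose(curl, 0.0, atol=1e-12)

    def test_affine_exactness(self):
        """Any affine field is reproduced exactly, hence its curl too."""
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(120, 3)) * 15
        jac = rng.normal(size=(3, 3))
        forces = pts @ jac.T + rng.normal(size=3)
        curl = curl_field(pts, forces, k_neighbors=10)
        expected = np.array([jac[2, 1] - jac[1, 2],
                             jac[0, 2] - jac[2, 0],
                             jac[1, 0] - jac[0, 1]])
        np.testing.assert_allclose(curl, np.tile(expected, (len(pts), 1)), atol=1e-9)

    def test_polynomial_field_converges_with_grid_refinement(self):
        """Error of the estimated curl shrinks as sampling densifies."""
        def run(n_side):
            g = np.linspace(-1.0, 1.0, n_side)
            x, y, z = np.meshgrid(g, g, g, indexing="ij")
            pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
            forces = np.column_stack([pts[:, 1] ** 2, pts[:, 2] ** 2, pts[:, 0] ** 2])
            analytic = np.column_stack([-2 * pts[:, 2], -2 * pts[:, 0], -2 * pts[:, 1]])
            est = curl_field(pts, forces, k_neighbors=14)
            return np.abs(est - analytic).max()

        coarse, fine = run(6), run(12)
        assert fine < coarse

    def test_collinear_points_raise(self):
        pts = np.column_stack([np.linspace(0, 10, 30), np.zeros(30), np.zeros(30)])
        forces = np.ones_like(pts)
        with pytest.raises(DegenerateNeighborhoodError):
            curl_field(pts, forces, k_neighbors=5)

    def test_requires_enough_points(self):
        with pytest.raises(ValueError):
            curl_field(np.zeros((4, 3)), np.zeros((4, 3)), k_neighbors=4)


class TestVortex:
    def test_argmin_selection(self):
        pts = np.eye(3)
        curls = np.array([[0.5, 0, 0], [0.0, 0, 0], [0.2, 0, 0]])
        forces = np.ones((3, 3))
        idx, pos = find_vortex(pts, curls, forces)
        assert idx == 1
        np.testing.assert_array_equal(pos, pts[1])

    def test_tie_breaks_on_force_then_index(self):
        pts = np.arange(9.0).reshape(3, 3)
        curls = np.zeros((3, 3))
        forces = np.array([[2.0, 0, 0], [1.0, 0, 0], [1.0, 0, 0]])
        idx, _ = find_vortex(pts, curls, forces)
        assert idx == 1  # smallest force wins; lower index among equal forces

    def test_vortex_near_mass_center_for_rotational_displacement(self, default_phantom):
        """A rotationally displaced identical pair puts the vortex well inside the cloud."""
        moving = displace(default_phantom,
                          RigidTransform([0, 0, 30], [0, 0, 0], default_phantom.centroid()))
        _, _, pos = analyze_force_field(moving, default_phantom)
        dists = np.linalg.norm(moving.points - moving.centroid(), axis=1)
        assert np.linalg.norm(pos - moving.centroid()) < np.percentile(dists, 90)


def test_analyze_force_field_samples_are_consistent(default_phantom):
    moving = displace(default_phantom,
                      RigidTransform([0, 0, 20], [0, 0, 0], default_phantom.centroid()))
    samples, idx, pos = analyze_force_field(moving, default_phantom)
    assert len(samples) == moving.n_attributed
    np.testing.assert_array_equal(samples.force, -samples.gradient)
    assert np.all((samples.potential >= 0) & (samples.potential < 1))
    np.testing.assert_allclose(samples.curl_magnitude,
                               np.linalg.norm(samples.curl, axis=1), atol=1e-12)
    np.testing.assert_array_equal(pos, samples.positions[idx])
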