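import numpy as np
import pytest

from vfareg.core import RigidTransform, apply_transform, compose_transforms
from vfareg.errors import MissingClassError
from vfareg.matching import closest_points
from vfareg.fields import total_energy
from vfareg.registration import (
    RegistrationConfig,
    energy_of_params,
    jacobian_of_params,
    register_gf,
    register_vfa,
)
from vfareg.synthetic import displace

from .conftest import rotation_angle_deg


class TestEnergyOfParams:
    def test_zero_params_on_identical_clouds(self, small_phantom):
        for pivot in (np.zeros(3), small_phantom.centroid()):
            assert energy_of_params(np.zeros(6), pivot, small_phantom,
                                    small_phantom) == 0.0

    def test_pivot_irrelevant_at_zero_params(self, small_phantom):
        moved = apply_transform(small_phantom, RigidTransform([5, 0, 0], [2, 0, 0]))
        e_a = energy_of_params(np.zeros(6), np.zeros(3), small_phantom, moved)
        e_b = energy_of_params(np.zeros(6), [100, -50, 25], small_phantom, moved)
        assert e_a == e_b

    def test_matches_directly_displaced_energy(self, small_phantom):
        """Energy at the generating parameters equals total_energy of displaced clouds."""
        cfg = RegistrationConfig()
        pivot = np.array([10.0, -5.0, 20.0])
        params = np.array([12.0, -7.0, 30.0, 4.0, 1.0, -6.0])
        value = energy_of_params(params, pivot, small_phantom, small_phantom, cfg)
        displaced = apply_transform(
            small_phantom, RigidTransform(params[:3], params[3:], pivot))
        direct = total_energy(closest_points(displaced, small_phantom), cfg.energy_params)
        assert value == pytest.approx(direct, rel=1e-12)

    def test_missing_class_propagates(self, small_phantom):
        from vfareg.core import AttributedPointCloud

        bad = AttributedPointCloud(small_phantom.points,
                                   np.where(small_phantom.attributes > 0, 99, 0))
        with pytest.raises(MissingClassError):
            energy_of_params(np.zeros(6), np.zeros(3), small_phantom, bad)


class TestJacobian:
    def test_zero_at_perfect_alignment(self, small_phantom):
        jac = jacobian_of_params(np.zeros(6), small_phantom.centroid(),
                                 small_phantom, small_phantom)
        np.testing.assert_allclose(jac, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_central_finite_differences(self, seed, small_phantom):
        rng = np.random.default_rng(seed)
        pivot = small_phantom.centroid() + rng.normal(size=3) * 10
        params = np.concatenate([rng.uniform(-20, 20, 3), rng.uniform(-10, 10, 3)])
        cfg = RegistrationConfig()
        jac = jacobian_of_params(params, pivot, small_phantom, small_phantom, cfg)
        h = 1e-5
        fd = np.zeros(6)
        for k in range(6):
            for sign in (1.0, -1.0):
                p = params.copy()
                p[k] += sign * h
                fd[k] += sign * energy_of_params(p, pivot, small_phantom,
                                                 small_phantom, cfg)
        fd /= 2 * h
        np.testing.assert_allclose(jac, fd, rtol=1e-4, atol=1e-8)

    def test_translation_components_reduce_to_pointwise_gradients(self, small_phantom):
        """dE/dt equals the summed per-point potential gradients."""
        from vfareg.fields import potential_gradient

        cfg = RegistrationConfig()
        moved = apply_transform(small_phantom, RigidTransform([7, -3, 11], [5, -2, 4]))
        jac = jacobian_of_params(np.zeros(6), np.zeros(3), small_phantom, moved, cfg)
        corr = closest_points(moved, small_phantom, cfg.energy_params)
        fs = potential_gradient(moved, small_phantom, corr, cfg.energy_params)
        np.testing.assert_allclose(jac[3:], fs.gradient.sum(axis=0), rtol=1e-10)


class TestRegisterVFA:
    def test_already_aligned_stays_aligned(self, small_phantom):
        res = register_vfa(small_phantom, small_phantom)
        assert res.converged
        assert res.residual <= 1e-9
        assert rotation_angle_deg(res.transform.matrix) < 1e-6
        assert np.linalg.norm(res.transform.origin_translation) < 1e-6
        assert len(res.energy_trace) <= 3  # at most a couple of accepted steps

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_recovers_large_displacements(self, default_phantom, seed):
        """Noise-free identical pair: recovery within 0.1 deg / 0.1 mm."""
        rng = np.random.default_rng(100 + seed)
        truth = RigidTransform(rng.uniform(0, 360, 3), rng.uniform(-200, 200, 3))
        moving = displace(default_phantom, truth)
        res = register_vfa(default_phantom, moving)
        net = compose_transforms(res.transform, truth)
        assert res.residual <= 1e-3
        assert rotation_angle_deg(net.matrix) < 0.1
        assert np.linalg.norm(net.origin_translation) < 0.1

    def test_noisy_scan_registers_with_clinical_accuracy(self, scan_pair):
        """Scan-to-model registration: TRE at anterior targets under 1.5 mm."""
        from vfareg.evaluation import anterior_targets, tre

        phantom, scan = scan_pair
        truth = RigidTransform([25, -40, 60], [30, -20, 10], scan.centroid())
        moving = displace(scan, truth)
        res = register_vfa(phantom, moving)
        assert res.residual > 0  # noise forbids a perfect fit
        targets, labels = anterior_targets()
        report = tre(targets, truth.apply(targets), res.transform, labels)
        assert report.max <= 1.5

    def test_energy_trace_non_increasing_and_residual_is_last(self, default_phantom):
        moving = displace(default_phantom,
                          RigidTransform([40, 160, -80], [90, -120, 30]))
        res = register_vfa(default_phantom, moving)
        trace = np.asarray(res.energy_trace)
        assert np.all(np.diff(trace) <= 1e-12)
        assert res.residual == trace[-1]

    def test_initial_transform_is_composed_into_result(self, small_phantom):
        init = RigidTransform([0, 0, 45], [10, 0, 0])
        moved = displace(small_phantom, init.inverse())
        res = register_vfa(small_phantom, moved, initial_transform=init)
        final = apply_transform(moved, res.transform)
        assert np.abs(final.points - small_phantom.points).max() < 0.1


class TestRegisterGF:
    def test_aligned_start_stays_aligned(self, small_phantom):
        res = register_gf(small_phantom, small_phantom)
        assert res.residual <= 1e-9
        assert rotation_angle_deg(res.transform.matrix) < 1e-6

    def test_small_rotation_converges_near_vfa(self, scan_pair):
        phantom, scan = scan_pair
        moving = displace(scan, RigidTransform([0, 0, 8], np.zeros(3), scan.centroid()))
        res_gf = register_gf(phantom, moving)
        res_vfa = register_vfa(phantom, moving)
        assert res_gf.residual == pytest.approx(res_vfa.residual, rel=0.1)

    def test_fails_from_half_turn_where_vfa_succeeds(self, scan_pair):
        """The constructed failure case: a 180-degree flip traps the GF baseline."""
        phantom, scan = scan_pair
        moving = displace(scan, RigidTransform([0, 0, 180], np.zeros(3), scan.centroid()))
        res_gf = register_gf(phantom, moving)
        res_vfa = register_vfa(phantom, moving)
        assert res_gf.residual > 5 * res_vfa.residual

    def test_gf_pivot_is_origin(self, small_phantom):
        res = register_gf(small_phantom, small_phantom)
        np.testing.assert_array_equal(res.pivot_used, np.zeros(3))


def test_result_dict_schema(small_phantom):
    res = register_vfa(small_phantom, small_phantom)
    d = res.to_dict()
    assert set(d) == {"method", "transform", "residual", "iterations", "converged",
                      "pivot_used", "energy_trace"}
    assert d["transform"]["axis_order"] == "xyz-extrinsic"
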