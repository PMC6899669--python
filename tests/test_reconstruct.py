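import numpy as np
import pytest

from diffct import (DetectorGeometry, EllipsePrimitive, IterativeConfig,
                    ProjectionStack, ProjectorConfig, VolumeGeometry,
                    VolumeGrid, cone_beam, explicit_system_matrix, fan_beam,
                    fbp, forward_project, iterative_tv, parallel_beam,
                    rasterize, shepp_logan, tv_value_and_gradient)


def _rmse(a, b, dyn):
    return np.sqrt(np.mean((a - b) ** 2)) / dyn


class TestFBP:
    def test_zero_sinogram_reconstructs_zero(self, tiny_parallel):
        g = tiny_parallel
        rec = fbp(ProjectionStack(np.zeros(g.stack_shape), g), g)
        assert not rec.values.any()

    def test_parallel_self_consistency_recovers_absolute_values(self):
        vg = VolumeGeometry((128, 128), (1.0, 1.0))
        ph = shepp_logan(vg)
        g = parallel_beam(vg, DetectorGeometry((185,), (1.0,)), 180, np.pi)
        rec = fbp(forward_project(ph, g), g)
        dyn = ph.values.max() - ph.values.min()
        assert _rmse(rec.values, ph.values, dyn) < 0.05
        # absolute scale: interior grey value, not just structure
        assert rec.values[64, 64] == pytest.approx(ph.values[64, 64], abs=0.02)

    def test_more_views_do_not_increase_error(self):
        vg = VolumeGeometry((128, 128), (1.0, 1.0))
        ph = shepp_logan(vg)
        dyn = ph.values.max() - ph.values.min()
        errs = []
        for n_views in (90, 180):
            g = parallel_beam(vg, DetectorGeometry((185,), (1.0,)), n_views,
                              np.pi)
            rec = fbp(forward_project(ph, g), g)
            errs.append(_rmse(rec.values, ph.values, dyn))
        assert errs[1] <= errs[0]

    def test_fbp_is_linear_in_the_sinogram(self, rng):
        vg = VolumeGeometry((32, 32), (1.0, 1.0))
        g = parallel_beam(vg, DetectorGeometry((47,), (1.0,)), 24, np.pi)
        p = rng.standard_normal(g.stack_shape)
        a = fbp(ProjectionStack(4.0 * p, g), g).values
        b = 4.0 * fbp(ProjectionStack(p, g), g).values
        np.testing.assert_allclose(a, b, atol=1e-11)

    def test_fan_short_scan_self_consistency(self):
        vg = VolumeGeometry((128, 128), (1.0, 1.0))
        ph = shepp_logan(vg)
        g = fan_beam(vg, DetectorGeometry((307,), (1.0,)), 240,
                     sid=300.0, sdd=500.0)
        rec = fbp(forward_project(ph, g), g)
        dyn = ph.values.max() - ph.values.min()
        assert _rmse(rec.values, ph.values, dyn) < 0.07

    def test_fan_requires_short_scan_range(self):
        vg = VolumeGeometry((32, 32), (1.0, 1.0))
        g = fan_beam(vg, DetectorGeometry((47,), (1.0,)), 24,
                     sid=300.0, sdd=500.0, angular_range=np.pi)
        with pytest.raises(ValueError, match="short scan"):
            fbp(ProjectionStack(np.zeros(g.stack_shape), g), g)

    def test_fdk_central_slice_matches_fan_fbp(self):
        vg3 = VolumeGeometry((32, 32, 32), (1.0, 1.0, 1.0))
        prims = [EllipsePrimitive((0., 0., 0.), (12., 9., 14.), 0.3, 1.0),
                 EllipsePrimitive((4., -2., 0.), (4., 6., 10.), 0.0, 0.5)]
        vol3 = rasterize(prims, vg3, 2)
        sid, sdd = 250.0, 400.0
        g3 = cone_beam(vg3, DetectorGeometry((63, 63), (1.0, 1.0)), 90,
                       sid, sdd)
        rec3 = fbp(forward_project(vol3, g3), g3)
        # fan reconstruction of the z = 0 plane (between slices 15 and 16)
        vg2 = VolumeGeometry((32, 32), (1.0, 1.0))
        mid = 0.5 * (vol3.values[15] + vol3.values[16])
        g2 = fan_beam(vg2, DetectorGeometry((63,), (1.0,)), 90, sid, sdd)
        rec2 = fbp(forward_project(VolumeGrid(mid, vg2), g2), g2)
        mid3 = 0.5 * (rec3.values[15] + rec3.values[16])
        rel = np.linalg.norm(mid3 - rec2.values) / np.linalg.norm(rec2.values)
        assert rel < 0.02


class TestTotalVariation:
    def test_constant_volume_has_zero_value_and_gradient(self):
        vg = VolumeGeometry((9, 9), (1.0, 1.0))
        v, g = tv_value_and_gradient(VolumeGrid(np.full((9, 9), 3.7), vg))
        assert v == pytest.approx(0.0, abs=1e-9)
        assert np.max(np.abs(g.values)) < 1e-9

    def test_step_edge_value_approaches_edge_length(self):
        vg = VolumeGeometry((16, 16), (1.0, 1.0))
        vol = np.zeros((16, 16))
        vol[:, 8:] = 1.0
        v, _ = tv_value_and_gradient(VolumeGrid(vol, vg), epsilon=1e-8)
        assert v == pytest.approx(16.0, rel=1e-6)

    @pytest.mark.parametrize("shape", [(7, 9), (5, 6, 4)])
    def test_gradient_matches_finite_differences(self, shape, rng):
        vg = VolumeGeometry(shape, (1.0,) * len(shape))
        x = rng.standard_normal(shape)
        eps = 1e-3
        _, g = tv_value_and_gradient(VolumeGrid(x, vg), eps)
        h = 1e-6
        flat = x.ravel()
        idx = rng.choice(flat.size, size=40, replace=False)
        for i in idx:
            xp, xm = flat.copy(), flat.copy()
            xp[i] += h
            xm[i] -= h
            vp, _ = tv_value_and_gradient(VolumeGrid(xp.reshape(shape), vg), eps)
            vm, _ = tv_value_and_gradient(VolumeGrid(xm.reshape(shape), vg), eps)
            assert (vp - vm) / (2 * h) == pytest.approx(g.values.ravel()[i],
                                                        abs=1e-5)

    def test_rejects_nonpositive_epsilon(self):
        vg = VolumeGeometry((4, 4), (1.0, 1.0))
        with pytest.raises(ValueError):
            tv_value_and_gradient(VolumeGrid(np.zeros((4, 4)), vg), 0.0)


class TestIterativeTV:
    def test_single_voxel_single_ray_reaches_least_squares_solution(self):
        vg = VolumeGeometry((1, 1), (1.0, 1.0))
        g = parallel_beam(vg, DetectorGeometry((1,), (1.0,)), 1, np.pi)
        A = explicit_system_matrix(g)
        p = np.array([[3.0]])
        x_star = float(np.linalg.lstsq(A, p.ravel(), rcond=None)[0][0])
        cfg = IterativeConfig(lambda_tv=0.0, step_size=0.4, iterations=200)
        rec, _ = iterative_tv(ProjectionStack(p, g), g, cfg)
        assert abs(rec.values[0, 0] - x_star) < 1e-6

    def test_objective_trace_is_non_increasing(self, rng):
        vg = VolumeGeometry((16, 16), (1.0, 1.0))
        g = parallel_beam(vg, DetectorGeometry((23,), (1.0,)), 12, np.pi)
        p = np.abs(rng.standard_normal(g.stack_shape))
        cfg = IterativeConfig(lambda_tv=0.5, step_size=1.0, iterations=40)
        _, trace = iterative_tv(ProjectionStack(p, g), g, cfg)
        assert np.all(np.diff(trace[:, 2]) <= 1e-10)

    def test_noiseless_residual_drops_by_an_order_of_magnitude(self):
        vg = VolumeGeometry((64, 64), (1.0, 1.0))
        ph = shepp_logan(vg)
        g = parallel_beam(vg, DetectorGeometry((91,), (1.0,)), 30, np.pi)
        s = forward_project(ph, g)
        cfg = IterativeConfig(lambda_tv=0.0, step_size=2e-3, iterations=60)
        _, trace = iterative_tv(s, g, cfg)
        assert np.sqrt(trace[-1, 0] / trace[0, 0]) <= 0.1

    def test_sparse_view_tv_beats_fbp(self):
        vg = VolumeGeometry((64, 64), (1.0, 1.0))
        ph = shepp_logan(vg)
        g = parallel_beam(vg, DetectorGeometry((91,), (1.0,)), 30, np.pi)
        s = forward_project(ph, g)
        dyn = ph.values.max() - ph.values.min()
        err_fbp = _rmse(fbp(s, g).values, ph.values, dyn)
        cfg = IterativeConfig(lambda_tv=1.0, step_size=2e-3, iterations=80,
                              init="fbp")
        rec, _ = iterative_tv(s, g, cfg)
        assert _rmse(rec.values, ph.values, dyn) < err_fbp

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            IterativeConfig(lambda_tv=-1.0)
        with pytest.raises(ValueError):
            IterativeConfig(step_size=0.0)
        with pytest.raises(ValueError):
            IterativeConfig(init="random")
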