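import numpy as np
import pytest

from diffct import (DetectorGeometry, EllipsePrimitive, ProjectionStack,
                    ProjectorConfig, VolumeGeometry, VolumeGrid,
                    analytic_sinogram, back_project, back_project_transpose,
                    cone_beam, explicit_system_matrix, fan_beam,
                    forward_project, forward_project_transpose, parallel_beam,
                    rasterize)


def _grid(geom, values):
    return VolumeGrid(values, geom.volume)


@pytest.fixture(scope="module")
def geoms(tiny_parallel, tiny_fan, tiny_cone):
    return {"parallel2d": tiny_parallel, "fan2d": tiny_fan, "cone3d": tiny_cone}


class TestForwardProject:
    @pytest.mark.parametrize("beam", ["parallel2d", "fan2d", "cone3d"])
    def test_zero_volume_projects_to_zero(self, geoms, beam):
        g = geoms[beam]
        sino = forward_project(_grid(g, np.zeros(g.volume.shape)), g)
        assert not sino.values.any()

    @pytest.mark.parametrize("beam", ["parallel2d", "fan2d", "cone3d"])
    def test_linearity(self, geoms, beam, rng):
        g = geoms[beam]
        x = rng.standard_normal(g.volume.shape)
        z = rng.standard_normal(g.volume.shape)
        a, b = 2.5, -1.25
        lhs = forward_project(_grid(g, a * x + b * z), g).values
        rhs = (a * forward_project(_grid(g, x), g).values
               + b * forward_project(_grid(g, z), g).values)
        np.testing.assert_allclose(lhs, rhs, atol=1e-11)

    def test_single_voxel_axis_aligned_ray_integrates_its_extent(self):
        # 1-voxel volume, ray through its centre: line integral = spacing
        vol = VolumeGeometry((1, 1), (2.0, 2.0))
        det = DetectorGeometry((1,), (1.0,))
        for start in (0.0, np.pi / 2):
            g = parallel_beam(vol, det, 1, np.pi, start_angle=start)
            sino = forward_project(_grid(g, np.ones((1, 1))), g)
            assert sino.values[0, 0] == pytest.approx(2.0, rel=0.02)

    def test_centered_disk_sinogram_is_rotation_invariant(self):
        # voxelization anisotropy concentrates at the tangent rays, where a
        # sharp disk is not representable on the grid; rays clear of the
        # tangency band must agree across views to well under a percent
        vg = VolumeGeometry((128, 128), (1.0, 1.0))
        g = parallel_beam(vg, DetectorGeometry((185,), (1.0,)), 48, np.pi)
        r = 40.3
        vol = rasterize([EllipsePrimitive((0., 0.), (r, r))], vg, 8)
        sino = forward_project(vol, g).values
        dev = np.abs(sino - sino[0])
        peak = sino.max()
        inner = np.abs(g.detector.coordinates()) < r - 3.0
        assert dev[:, inner].max() < 0.005 * peak
        assert dev.max() < 0.015 * peak

    def test_halving_step_reduces_analytic_oracle_error(self):
        vg = VolumeGeometry((64, 64), (1.0, 1.0))
        g = parallel_beam(vg, DetectorGeometry((91,), (1.0,)), 24, np.pi)
        ell = [EllipsePrimitive((0., 0.), (20.4, 20.4))]
        vol = rasterize(ell, vg, 8)
        oracle = analytic_sinogram(ell, g).values
        errs = [np.abs(forward_project(vol, g, ProjectorConfig(sf)).values
                       - oracle).mean() for sf in (1.0, 0.5, 0.25)]
        assert errs[2] < errs[0]

    def test_geometry_mismatch_rejected(self, tiny_parallel):
        wrong = VolumeGrid(np.zeros((8, 8)), VolumeGeometry((8, 8), (1., 1.)))
        with pytest.raises(ValueError, match="geometry"):
            forward_project(wrong, tiny_parallel)

    def test_cone_without_matrices_rejected(self):
        from diffct.geometry import ScanGeometry
        vol = VolumeGeometry((8, 8, 8), (1., 1., 1.))
        det = DetectorGeometry((10, 10), (1., 1.))
        g = ScanGeometry("cone3d", vol, det, np.array([0.0]),
                         source_isocenter_distance=50.,
                         source_detector_distance=80.)
        with pytest.raises(ValueError, match="matrices"):
            forward_project(_grid(g, np.zeros((8, 8, 8))), g)


class TestBackProject:
    def test_zero_stack_gives_zero_volume(self, tiny_parallel):
        g = tiny_parallel
        vol = back_project(ProjectionStack(np.zeros(g.stack_shape), g), g)
        assert not vol.values.any()

    def test_single_view_ones_sinogram_deposits_dbeta(self):
        vg = VolumeGeometry((8, 8), (1.0, 1.0))
        g = parallel_beam(vg, DetectorGeometry((15,), (1.0,)), 1, np.pi)
        vol = back_project(ProjectionStack(np.ones(g.stack_shape), g), g)
        np.testing.assert_allclose(vol.values, g.angle_increment, rtol=1e-12)

    def test_distance_weighting_scales_fan_contributions(self, tiny_fan):
        g = tiny_fan
        ones = ProjectionStack(np.ones(g.stack_shape), g)
        plain = back_project(ones, g, ProjectorConfig(0.5, False)).values
        weighted = back_project(ones, g, ProjectorConfig(0.5, True)).values
        # voxels nearer the source than the isocenter get weight > 1
        assert (weighted > plain).any() and (weighted < plain).any()


class TestSystemMatrixOracle:
    def test_matrix_matches_operator_and_transposes(self, geoms, rng):
        for beam in ("parallel2d", "fan2d", "cone3d"):
            g = geoms[beam]
            A = explicit_system_matrix(g)
            x = rng.standard_normal(g.volume.n_voxels)
            y = rng.standard_normal(A.shape[0])
            fp = forward_project(_grid(g, x.reshape(g.volume.shape)), g).values
            rel = np.linalg.norm(A @ x - fp.ravel()) / np.linalg.norm(fp)
            assert rel < 1e-10
            at = forward_project_transpose(
                ProjectionStack(y.reshape(g.stack_shape), g), g).values
            rel_t = (np.linalg.norm(A.T @ y - at.ravel())
                     / np.linalg.norm(A.T @ y))
            assert rel_t < 1e-10

    def test_matched_dot_product_identity(self, tiny_parallel, rng):
        g = tiny_parallel
        x = rng.standard_normal(g.volume.shape)
        y = rng.standard_normal(g.stack_shape)
        ax = forward_project(_grid(g, x), g).values
        aty = forward_project_transpose(ProjectionStack(y, g), g).values
        lhs = np.vdot(ax, y)
        rhs = np.vdot(x, aty)
        assert abs(lhs - rhs) / abs(lhs) < 1e-12

    def test_voxel_driven_pair_is_unmatched_but_close(self, tiny_parallel, rng):
        g = tiny_parallel
        x = rng.standard_normal(g.volume.shape)
        y = rng.standard_normal(g.stack_shape)
        ax = forward_project(_grid(g, x), g).values
        by = back_project(ProjectionStack(y, g), g).values / g.angle_increment
        disc = (abs(np.vdot(ax, y) - np.vdot(x, by))
                / (np.linalg.norm(ax) * np.linalg.norm(y)))
        assert disc < 0.05

    def test_backprojector_scatter_is_its_exact_transpose(self, geoms, rng):
        for beam in ("parallel2d", "fan2d", "cone3d"):
            g = geoms[beam]
            x = rng.standard_normal(g.volume.shape)
            y = rng.standard_normal(g.stack_shape)
            by = back_project(ProjectionStack(y, g), g).values
            btx = back_project_transpose(_grid(g, x), g).values
            lhs = np.vdot(x, by)
            rhs = np.vdot(btx, y)
            assert abs(lhs - rhs) / abs(lhs) < 1e-12

    def test_refuses_oversized_problems(self):
        vg = VolumeGeometry((64, 64), (1.0, 1.0))
        g = parallel_beam(vg, DetectorGeometry((91,), (1.0,)), 360, np.pi)
        with pytest.raises(ValueError, match="refus"):
            explicit_system_matrix(g, max_entries=10_000)


class TestConeFanConsistency:
    def test_central_row_approaches_fan_projection(self):
        # z-symmetric phantom, small cone angle: central detector row of the
        # cone projection matches the fan projection of the central slice
        vg3 = VolumeGeometry((32, 32, 32), (1.0, 1.0, 1.0))
        prims = [EllipsePrimitive((0., 0., 0.), (12., 9., 14.), 0.3, 1.0)]
        vol3 = rasterize(prims, vg3, 2)
        sid, sdd = 500.0, 800.0
        g3 = cone_beam(vg3, DetectorGeometry((63, 63), (1.0, 1.0)), 12,
                       sid, sdd)
        cone_sino = forward_project(vol3, g3).values[:, 31, :]

        vg2 = VolumeGeometry((32, 32), (1.0, 1.0))
        # central slice of the volume lattice sits at z = +0.5 for 32 voxels;
        # average the two central slices to land on z = 0 like the detector row
        mid = 0.5 * (vol3.values[15] + vol3.values[16])
        g2 = fan_beam(vg2, DetectorGeometry((63,), (1.0,)), 12, sid, sdd,
                      angular_range=g3.angular_range)
        fan_sino = forward_project(VolumeGrid(mid, vg2), g2).values
        rel = (np.linalg.norm(cone_sino - fan_sino)
               / np.linalg.norm(fan_sino))
        assert rel < 0.02


class TestProjectorConfig:
    @pytest.mark.parametrize("sf", [0.0, 1.5, -0.5])
    def test_rejects_bad_step_fraction(self, sf):
        with pytest.raises(ValueError):
            ProjectorConfig(step_fraction=sf)
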