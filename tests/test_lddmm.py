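"""LDDMM core: flows, geodesic shooting, varifold metric, registration."""

import numpy as np
import pytest

from mtlmorph.containers import LabelVolume, TriMesh
from mtlmorph.lddmm import (
    Diffeomorphism,
    KernelConfig,
    VelocityField,
    dice,
    flow_points,
    flow_points_inverse,
    gauss_kernel,
    jacobian_map,
    register_images,
    register_surfaces,
    rkhs_norm,
    shoot,
    shoot_backward,
    shoot_states,
    varifold_distance,
    varifold_loss_and_grad,
    warp_label_volume,
    _elements,
    _varifold_product,
)


class TestFlowPoints:
    def test_zero_velocity_is_identity(self, rng):
        q = rng.normal(size=(5, 3))
        vf = VelocityField(np.zeros((11, 4, 3)), np.zeros((11, 4, 3)))
        traj = flow_points(vf, q)
        assert traj.shape == (11, 5, 3)
        np.testing.assert_allclose(traj[-1], q)

    def test_constant_velocity_translates_exactly(self, rng):
        u = np.array([1.0, -2.0, 0.5])
        vf = VelocityField.from_analytic(lambda x, t: np.tile(u, (len(x), 1)), n_timesteps=7)
        q = rng.normal(size=(6, 3))
        traj = flow_points(vf, q)
        np.testing.assert_allclose(traj[-1], q + u, rtol=1e-12)

    def test_step_refinement_converges(self, rng):
        # two interacting particles: the geodesic genuinely curves
        q0 = np.array([[0.0, 0.0, 0.0], [1.5, 0.5, 0.0]])
        p0 = np.array([[1.0, 0.5, 0.0], [-0.3, 0.8, 0.2]])
        ends = {}
        for T in (20, 200, 1600):
            qs, _ = shoot_states(q0, p0, sigma=2.0, n_timesteps=T)
            ends[T] = qs[-1]
        err_coarse = np.linalg.norm(ends[20] - ends[1600])
        err_fine = np.linalg.norm(ends[200] - ends[1600])
        assert err_fine < err_coarse / 5  # first-order stepping

    def test_nonfinite_velocity_reports_timestep(self):
        def bad(x, t):
            v = np.zeros_like(x)
            if t >= 2:
                v[:] = np.nan
            return v

        vf = VelocityField.from_analytic(bad, n_timesteps=5)
        with pytest.raises(ValueError, match="timestep 2"):
            flow_points(vf, np.zeros((2, 3)))


class TestRkhsNorm:
    def test_zero_field(self):
        vf = VelocityField(np.zeros((3, 4, 3)), np.zeros((3, 4, 3)))
        assert rkhs_norm(vf) == 0.0

    def test_single_unit_vector_self_kernel(self):
        q = np.zeros((1, 1, 3))
        p = np.zeros((1, 1, 3))
        p[0, 0, 0] = 1.0
        vf = VelocityField(q, p, KernelConfig(sigma_V=3.0))
        assert rkhs_norm(vf) == pytest.approx(1.0)

    def test_matches_dense_quadratic_form(self, rng):
        q = rng.normal(size=(1, 7, 3)) * 3
        p = rng.normal(size=(1, 7, 3))
        cfg = KernelConfig(sigma_V=2.0)
        vf = VelocityField(q, p, cfg)
        K = np.exp(-((q[0][:, None] - q[0][None]) ** 2).sum(-1) / (2 * cfg.sigma_V**2))
        want = sum(
            K[i, j] * p[0, i] @ p[0, j] for i in range(7) for j in range(7)
        )
        assert rkhs_norm(vf) == pytest.approx(want)
        assert rkhs_norm(vf) >= 0


class TestVarifoldMetric:
    CFG = KernelConfig(sigma_W=1.5)

    def test_metric_axioms_and_flip_invariance(self, rng, blob_mesh):
        for k in range(10):
            a = blob_mesh(rng, subdivisions=1)
            b = blob_mesh(rng, subdivisions=1)
            daa = varifold_distance(a, a, self.CFG)
            dab = varifold_distance(a, b, self.CFG)
            dba = varifold_distance(b, a, self.CFG)
            assert daa == pytest.approx(0.0, abs=1e-8)
            assert dab >= 0
            assert dab == pytest.approx(dba, rel=1e-10)
            dflip = varifold_distance(a.flipped(), b.flipped(), self.CFG)
            assert dflip == pytest.approx(dab, rel=1e-9)

    def test_two_triangle_hand_expanded_oracle(self):
        a = TriMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        b = TriMesh([[0.5, 0.2, 0.3], [1.5, 0.2, 0.3], [0.5, 1.4, 0.8]], [[0, 1, 2]])
        sig = 1.5

        def product(m1, m2):
            c1 = m1.vertices.mean(0)
            c2 = m2.vertices.mean(0)
            n1 = 0.5 * np.cross(m1.vertices[1] - m1.vertices[0], m1.vertices[2] - m1.vertices[0])
            n2 = 0.5 * np.cross(m2.vertices[1] - m2.vertices[0], m2.vertices[2] - m2.vertices[0])
            K = np.exp(-((c1 - c2) ** 2).sum() / (2 * sig**2))
            return K * (n1 @ n2) ** 2 / (np.linalg.norm(n1) * np.linalg.norm(n2))

        want = product(a, a) + product(b, b) - 2 * product(a, b)
        got = varifold_distance(a, b, KernelConfig(sigma_W=sig))
        assert got == pytest.approx(want, rel=1e-12)

    def test_zero_area_faces_dropped_with_warning(self):
        a = TriMesh(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 2, 2]],
            [[0, 1, 2], [3, 3, 3]],  # second face degenerate
        )
        b = TriMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        with pytest.warns(UserWarning, match="zero-area"):
            d = varifold_distance(a, b, self.CFG)
        assert d == pytest.approx(0.0, abs=1e-12)


class TestGradients:
    """The hand-derived reverse-mode passes against finite differences."""

    def test_shooting_gradient_matches_finite_differences(self, rng):
        q0 = rng.normal(size=(5, 3))
        p0 = rng.normal(size=(5, 3)) * 0.3
        target = rng.normal(size=(5, 3))
        sigma, T = 1.5, 6

        def loss(p):
            qs, ps = shoot_states(q0, p, sigma, T)
            return 0.5 * ((qs[-1] - target) ** 2).sum(), qs, ps

        L, qs, ps = loss(p0)
        grad = shoot_backward(qs, ps, qs[-1] - target, sigma)
        eps = 1e-6
        for i, d in [(0, 0), (2, 1), (4, 2)]:
            pp = p0.copy()
            pp[i, d] += eps
            fd = (loss(pp)[0] - L) / eps
            assert grad[i, d] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_varifold_gradient_matches_finite_differences(self, rng, blob_mesh):
        a = TriMesh.icosphere(0, 1.0)
        b = blob_mesh(rng, subdivisions=0, radius=1.2)
        elems = _elements(b, drop_degenerate=True)
        self_term = _varifold_product(*elems, *elems, 1.0)
        L0, G = varifold_loss_and_grad(a, elems, self_term, 1.0)
        eps = 1e-6
        for i, d in [(0, 0), (5, 1), (11, 2)]:
            v = a.vertices.copy()
            v[i, d] += eps
            L1, _ = varifold_loss_and_grad(a.with_vertices(v), elems, self_term, 1.0)
            assert G[i, d] == pytest.approx((L1 - L0) / eps, rel=1e-3, abs=1e-9)


class TestShoot:
    CFG = KernelConfig(sigma_V=2.0, n_timesteps=50)

    def test_zero_momentum_is_identity(self, rng):
        q0 = rng.normal(size=(6, 3))
        d = shoot(np.zeros_like(q0), q0, self.CFG)
        pts = rng.normal(size=(10, 3))
        np.testing.assert_allclose(d.forward(pts), pts)

    def test_time_reversal_returns_to_start(self, rng):
        q0 = rng.normal(size=(6, 3)) * 2
        p0 = rng.normal(size=(6, 3)) * 0.4
        qs, ps = shoot_states(q0, p0, 2.0, 200)
        back, _ = shoot_states(qs[-1], -ps[-1], 2.0, 200)
        assert np.abs(back[-1] - q0).max() < 5e-2

    def test_inverse_consistency_on_grid(self, rng):
        q0 = rng.normal(size=(8, 3)) * 3
        p0 = rng.normal(size=(8, 3)) * 0.5
        d = shoot(p0, q0, KernelConfig(sigma_V=3.0, n_timesteps=20))
        g = np.stack(
            np.meshgrid(*(np.linspace(-4, 4, 5),) * 3, indexing="ij"), -1
        ).reshape(-1, 3)
        round_trip = d.inverse(d.forward(g))
        assert np.linalg.norm(round_trip - g, axis=1).mean() < 0.1


class TestJacobian:
    def test_identity_is_all_ones(self):
        d = Diffeomorphism.identity()
        det = jacobian_map(d, (6, 6, 6), (1.0, 1.0, 1.0))
        np.testing.assert_allclose(det, 1.0, atol=1e-12)

    def test_uniform_scaling_gives_s_cubed(self):
        s = 1.3
        d = Diffeomorphism(lambda x: s * x, lambda x: x / s)
        det = jacobian_map(d, (5, 5, 5), (1.0, 1.0, 1.0))
        np.testing.assert_allclose(det, s**3, rtol=1e-10)

    def test_det_integral_matches_deformed_volume(self, rng):
        # change of variables on a radial contraction about the grid center
        c = np.array([5.0, 5.0, 5.0])
        s = 0.9
        d = Diffeomorphism(lambda x: c + s * (x - c), lambda x: c + (x - c) / s)
        det = jacobian_map(d, (11, 11, 11), (1.0, 1.0, 1.0))
        np.testing.assert_allclose(det, s**3, rtol=1e-9)


class TestRegistration:
    def test_self_registration_is_identity_level(self, sphere_pair):
        src, _ = sphere_pair
        res = register_surfaces(src, src, KernelConfig(max_iter=30))
        assert res.final_fidelity <= 1e-10
        assert np.abs(res.initial_momentum).max() < 1e-8

    def test_energy_trace_non_increasing(self, sphere_pair):
        src, _ = sphere_pair
        tgt = src.with_vertices(src.vertices * 1.08)
        res = register_surfaces(src, tgt, KernelConfig(sigma_V=8.0, max_iter=40))
        tr = np.array(res.energy_trace)
        assert np.all(np.diff(tr) <= 1e-9 * np.abs(tr[:-1]) + 1e-12)
        assert res.final_fidelity < res.initial_fidelity

    def test_gd_optimizer_also_descends(self, sphere_pair):
        src, _ = sphere_pair
        tgt = src.with_vertices(src.vertices + np.array([1.0, 0, 0]))
        res = register_surfaces(
            src, tgt, KernelConfig(sigma_V=10.0, max_iter=25, optimizer="gd")
        )
        tr = np.array(res.energy_trace)
        assert np.all(np.diff(tr) <= 0)
        assert res.final_fidelity < 0.2 * res.initial_fidelity


def _ellipsoid_volume_on_grid(shape, spacing, axes, center, label=1):
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip((X, Y, Z), center, axes))
    grid = (q <= 1).astype(np.int16) * label
    return LabelVolume(grid, spacing, label_names={label: "blob"})


class TestImageRegistration:
    CFG = KernelConfig(sigma_V=6.0, sigma_W=3.0, n_timesteps=5, max_iter=40)

    def test_identity_case(self):
        vol = _ellipsoid_volume_on_grid((24, 24, 24), (1.0,) * 3, (6, 5, 4), (12, 12, 12))
        res = register_images(vol, vol, self.CFG)
        assert res.final_fidelity <= res.initial_fidelity + 1e-12
        assert np.abs(res.initial_momentum).max() < 1e-6

    def test_two_voxel_translation_recovered(self):
        a = _ellipsoid_volume_on_grid((28, 24, 24), (1.0,) * 3, (6, 5, 4), (11, 12, 12))
        b = _ellipsoid_volume_on_grid((28, 24, 24), (1.0,) * 3, (6, 5, 4), (13, 12, 12))
        res = register_images(a, b, self.CFG)
        disp = res.deformed_sources[0].vertices - res.control_points
        mean_disp = disp.mean(axis=0)
        assert np.linalg.norm(mean_disp - [2.0, 0.0, 0.0]) < 0.5
        warped = warp_label_volume(res.diffeo, a, like=b)
        assert dice(warped.grid == 1, b.grid == 1) > dice(a.grid == 1, b.grid == 1)

    def test_shrinkage_gives_jacobian_below_one(self):
        a = _ellipsoid_volume_on_grid((26, 26, 26), (1.0,) * 3, (7, 6, 5), (13, 13, 13))
        b = _ellipsoid_volume_on_grid((26, 26, 26), (1.0,) * 3, (5.6, 4.8, 4.0), (13, 13, 13))
        res = register_images(a, b, self.CFG)
        det = jacobian_map(res.diffeo, (10, 10, 10), (1.0,) * 3, origin=(8.0, 8.0, 8.0))
        assert det.min() > 0  # diffeomorphic
        assert det.mean() < 1.0  # net contraction inside the structure

    def test_empty_channel_dropped_with_warning(self):
        a = _ellipsoid_volume_on_grid((20, 20, 20), (1.0,) * 3, (5, 4, 4), (10, 10, 10))
        b = _ellipsoid_volume_on_grid((20, 20, 20), (1.0,) * 3, (5, 4, 4), (10, 10, 10))
        a.label_names[2] = "ghost"
        with pytest.warns(UserWarning, match="dropped"):
            res = register_images(a, b, self.CFG, labels=[1, 2])
        assert res.final_fidelity <= 1e-8
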