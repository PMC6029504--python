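"""Reconstruction algorithms against literal matrix-form oracles, plus
total-variation machinery."""

import numpy as np
import pytest

import dbtsim as d
import dbtsim.reconstruction as rc
from dbtsim.projection_model import ConfigurationError

from conftest import small_geometry

_WEIGHT_FLOOR = rc._WEIGHT_FLOOR


# ---------------------------------------------------------------------------
# literal dense-matrix reference implementations (test-side oracles)
# ---------------------------------------------------------------------------


def sart_matrix_reference(A, b, shape, n_iter, relax, nonneg, n_views):
    """SART as literal dense matrix arithmetic, one block per view."""
    n_rays = A.shape[0] // n_views
    x = np.zeros(A.shape[1])
    iterates = []
    for _ in range(n_iter):
        for v in range(n_views):
            Av = A[v * n_rays : (v + 1) * n_rays]
            bv = b[v * n_rays : (v + 1) * n_rays]
            r = Av.sum(axis=1)
            c = Av.sum(axis=0)
            resid = bv - Av @ x
            resid = np.where(r > _WEIGHT_FLOOR, resid / np.maximum(r, _WEIGHT_FLOOR), 0.0)
            upd = Av.T @ resid
            upd = np.where(c > _WEIGHT_FLOOR, upd / np.maximum(c, _WEIGHT_FLOOR), 0.0)
            x = x + relax * upd
            if nonneg:
                x = np.maximum(x, 0.0)
        iterates.append(x.reshape(shape).copy())
    return iterates


def mlem_matrix_reference(A, b, shape, n_iter, eps):
    """MLEM as literal dense matrix arithmetic."""
    b = np.maximum(b, 0.0)
    sens = A.T @ np.ones(A.shape[0])
    support = sens > _WEIGHT_FLOOR
    mean_sens = sens.mean()
    x = np.full(A.shape[1], max(b.mean() / mean_sens, eps))
    iterates = []
    for _ in range(n_iter):
        ratio = b / (A @ x + eps)
        x = np.where(support, x * (A.T @ ratio) / np.maximum(sens, _WEIGHT_FLOOR), 0.0)
        iterates.append(x.reshape(shape).copy())
    return iterates


def poisson_loglik(A, b, x, eps=1e-12):
    y = A @ x + eps
    return float(np.sum(b * np.log(y) - y))


@pytest.fixture(scope="module")
def consistent_instance(tiny_op_siddon, tiny_dense_matrix):
    """Noiseless consistent data from a random nonnegative 8³ volume."""
    rng = np.random.default_rng(11)
    x_true = rng.random(tiny_op_siddon.volume_shape) * 0.1
    proj = d.forward_project(x_true, tiny_op_siddon)
    return x_true, proj


class TestSART:
    def test_zero_data_zero_init_stays_zero(self, tiny_op):
        proj = d.ProjectionSet(
            data=np.zeros(tiny_op.projection_shape), geometry=tiny_op.geometry
        )
        out = d.sart(proj, tiny_op)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_matches_literal_matrix_implementation(
        self, tiny_op_siddon, tiny_dense_matrix, consistent_instance
    ):
        _, proj = consistent_instance
        captured = []
        d.sart(
            proj,
            tiny_op_siddon,
            rc.SARTParams(n_iterations=3),
            callback=lambda it, x: captured.append(x),
        )
        expected = sart_matrix_reference(
            tiny_dense_matrix,
            proj.data.ravel(),
            tiny_op_siddon.volume_shape,
            3,
            1.0,
            True,
            tiny_op_siddon.geometry.n_views,
        )
        for got, ref in zip(captured, expected):
            np.testing.assert_allclose(got, ref, rtol=1e-8, atol=1e-10)

    def test_residual_strictly_decreases_on_consistent_data(
        self, tiny_op_siddon, consistent_instance
    ):
        _, proj = consistent_instance
        out = d.sart(proj, tiny_op_siddon, rc.SARTParams(n_iterations=5))
        res = np.array(out.residual_history)
        assert np.all(np.diff(res) < 0)

    def test_default_iteration_count_recorded(self, tiny_op, consistent_instance):
        _, proj = consistent_instance
        out = d.sart(proj, tiny_op)
        assert out.params_used["n_iterations"] == 5

    def test_output_nonnegative(self, tiny_op):
        rng = np.random.default_rng(0)
        proj = d.ProjectionSet(
            data=rng.standard_normal(tiny_op.projection_shape),
            geometry=tiny_op.geometry,
        )
        out = d.sart(proj, tiny_op)
        assert out.data.min() >= 0.0


class TestMLEM:
    def test_zero_data_drives_image_to_zero(self, tiny_op):
        proj = d.ProjectionSet(
            data=np.zeros(tiny_op.projection_shape), geometry=tiny_op.geometry
        )
        out = d.mlem(proj, tiny_op)
        assert np.all(out.data <= 1e-8)

    def test_matches_literal_matrix_implementation(
        self, tiny_op_siddon, tiny_dense_matrix, consistent_instance
    ):
        _, proj = consistent_instance
        captured = []
        d.mlem(
            proj,
            tiny_op_siddon,
            rc.MLEMParams(n_iterations=3),
            callback=lambda it, x: captured.append(x),
        )
        expected = mlem_matrix_reference(
            tiny_dense_matrix,
            proj.data.ravel(),
            tiny_op_siddon.volume_shape,
            3,
            1e-10,
        )
        for got, ref in zip(captured, expected):
            np.testing.assert_allclose(got, ref, rtol=1e-8, atol=1e-12)

    def test_poisson_loglikelihood_nondecreasing(
        self, tiny_op_siddon, tiny_dense_matrix, consistent_instance
    ):
        _, proj = consistent_instance
        captured = []
        d.mlem(
            proj,
            tiny_op_siddon,
            rc.MLEMParams(n_iterations=8),
            callback=lambda it, x: captured.append(x),
        )
        b = proj.data.ravel()
        lls = [poisson_loglik(tiny_dense_matrix, b, x.ravel()) for x in captured]
        diffs = np.diff(lls)
        assert np.all(diffs >= -1e-8 * np.abs(lls[0]))

    def test_update_preserves_nonnegativity(self, tiny_op):
        rng = np.random.default_rng(5)
        proj = d.ProjectionSet(
            data=rng.random(tiny_op.projection_shape),
            geometry=tiny_op.geometry,
        )
        out = d.mlem(proj, tiny_op)
        assert out.data.min() >= 0.0
        assert out.params_used["n_iterations"] == 2


class TestFBP:
    def test_zero_projections_give_zero_volume(self, tiny_op):
        proj = d.ProjectionSet(
            data=np.zeros(tiny_op.projection_shape), geometry=tiny_op.geometry
        )
        out = d.fbp(proj, tiny_op)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_point_source_peak_at_true_location(self):
        g = d.make_geometry(
            15, 15.0, dict(detector_rows=80, detector_cols=96, pixel_pitch=0.5)
        )
        op = d.SystemOperator(g, (64, 64, 64), 0.5)
        vol = np.zeros(op.volume_shape)
        vol[32, 30, 35] = 1.0
        proj = d.forward_project(vol, op)
        out = d.fbp(proj, op)
        # in-plane maximum of the in-focus slice at the true voxel
        iy, ix = np.unravel_index(np.argmax(out.data[32]), out.data[32].shape)
        assert (iy, ix) == (30, 35)

    def test_shepp_logan_suppresses_high_frequencies(self, tiny_op):
        rng = np.random.default_rng(8)
        noisy = d.ProjectionSet(
            data=rng.standard_normal(tiny_op.projection_shape),
            geometry=tiny_op.geometry,
        )
        ramp = d.fbp(noisy, tiny_op, rc.FBPParams("ramp")).data
        sl = d.fbp(noisy, tiny_op, rc.FBPParams("shepp_logan")).data
        spec_r = np.abs(np.fft.rfft(ramp, axis=-1)) ** 2
        spec_s = np.abs(np.fft.rfft(sl, axis=-1)) ** 2
        hi = spec_r.shape[-1] // 2  # above half-Nyquist along the filter axis
        assert spec_s[..., hi:].sum() < spec_r[..., hi:].sum()

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            rc.FBPParams(kernel="hann")

    def test_deterministic(self, tiny_op):
        rng = np.random.default_rng(2)
        proj = d.ProjectionSet(
            data=rng.random(tiny_op.projection_shape), geometry=tiny_op.geometry
        )
        a = d.fbp(proj, tiny_op).data
        b = d.fbp(proj, tiny_op).data
        np.testing.assert_array_equal(a, b)


class TestTotalVariation:
    def test_constant_volume_has_zero_tv(self):
        assert d.total_variation(np.full((5, 5, 5), 3.7)) == 0.0

    def test_single_plane_step(self):
        n, h = 6, 0.25
        vol = np.zeros((n, n, n))
        vol[3:] = h  # one axis-aligned step across a full plane
        assert d.total_variation(vol) == pytest.approx(h * n * n)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(4)
        vol = rng.random((6, 6, 6))
        tv = 0.0
        nz, ny, nx = vol.shape
        for k in range(nz):
            for i in range(ny):
                for j in range(nx):
                    gz = vol[k + 1, i, j] - vol[k, i, j] if k < nz - 1 else 0.0
                    gy = vol[k, i + 1, j] - vol[k, i, j] if i < ny - 1 else 0.0
                    gx = vol[k, i, j + 1] - vol[k, i, j] if j < nx - 1 else 0.0
                    tv += np.sqrt(gz**2 + gy**2 + gx**2)
        assert d.total_variation(vol) == pytest.approx(tv, rel=1e-10)


class TestTVGradient:
    def test_constant_volume_zero_gradient(self):
        np.testing.assert_allclose(
            d.tv_gradient(np.full((4, 4, 4), 2.0)), 0.0, atol=1e-6
        )

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(6)
        vol = rng.random((5, 5, 5))
        grad = d.tv_gradient(vol)
        h = 1e-6
        for idx in [(0, 0, 0), (2, 3, 1), (4, 4, 4), (1, 2, 2)]:
            plus = vol.copy()
            plus[idx] += h
            minus = vol.copy()
            minus[idx] -= h
            fd = (d.total_variation(plus) - d.total_variation(minus)) / (2 * h)
            assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_shift_invariance(self):
        rng = np.random.default_rng(7)
        vol = rng.random((5, 5, 5))
        np.testing.assert_allclose(
            d.tv_gradient(vol), d.tv_gradient(vol + 13.5), rtol=0, atol=1e-9
        )


class TestASDPOCS:
    def _sart_trajectory_with_beta_schedule(self, proj, op, n_iter, beta, beta_red):
        """POCS-only reference: repeated single SART sweeps with the decaying
        relaxation schedule used inside ASD-POCS."""
        x = np.zeros(op.volume_shape)
        for k in range(n_iter):
            out = d.sart(
                proj,
                op,
                rc.SARTParams(n_iterations=1, relaxation=beta * beta_red**k),
                x0=x,
            )
            x = out.data
        return x

    def test_ng_zero_is_bitwise_pocs_only(self, tiny_op, consistent_instance):
        _, proj_sid = consistent_instance
        proj = d.ProjectionSet(data=proj_sid.data, geometry=tiny_op.geometry)
        params = rc.ASDPOCSParams(n_iterations=4, ng=0)
        out = d.asd_pocs(proj, tiny_op, params)
        ref = self._sart_trajectory_with_beta_schedule(
            proj, tiny_op, 4, params.beta, params.beta_red
        )
        np.testing.assert_array_equal(out.data, ref)

    def test_vanishing_alpha_recovers_sart_trajectory(
        self, tiny_op, consistent_instance
    ):
        _, proj_sid = consistent_instance
        proj = d.ProjectionSet(data=proj_sid.data, geometry=tiny_op.geometry)
        params = rc.ASDPOCSParams(n_iterations=5, alpha=1e-12)
        out = d.asd_pocs(proj, tiny_op, params)
        ref = self._sart_trajectory_with_beta_schedule(
            proj, tiny_op, 5, params.beta, params.beta_red
        )
        assert np.max(np.abs(out.data - ref)) < 1e-6

    def test_defaults_recorded(self, tiny_op, consistent_instance):
        _, proj_sid = consistent_instance
        proj = d.ProjectionSet(data=proj_sid.data, geometry=tiny_op.geometry)
        out = d.asd_pocs(proj, tiny_op)
        assert out.params_used["alpha"] == 0.002
        assert out.params_used["ng"] == 25
        assert out.params_used["n_iterations"] == 5
        assert len(out.tv_history) == 5

    def test_histories_and_positivity(self, tiny_op):
        rng = np.random.default_rng(9)
        proj = d.ProjectionSet(
            data=rng.random(tiny_op.projection_shape) * 0.5,
            geometry=tiny_op.geometry,
        )
        out = d.asd_pocs(proj, tiny_op, rc.ASDPOCSParams(n_iterations=3))
        assert out.data.min() >= 0.0
        assert len(out.residual_history) == 3
        assert len(out.tv_history) == 3


class TestDeterminismAndDispatch:
    @pytest.mark.parametrize("algorithm", ["fbp", "sart", "mlem", "asd_pocs"])
    def test_reconstruction_is_deterministic(self, tiny_op, algorithm):
        rng = np.random.default_rng(1)
        proj = d.ProjectionSet(
            data=rng.random(tiny_op.projection_shape) * 0.3,
            geometry=tiny_op.geometry,
        )
        a = d.reconstruct(algorithm, proj, tiny_op)
        b = d.reconstruct(algorithm, proj, tiny_op)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unknown_algorithm_rejected(self, tiny_op):
        proj = d.ProjectionSet(
            data=np.zeros(tiny_op.projection_shape), geometry=tiny_op.geometry
        )
        with pytest.raises(ConfigurationError):
            d.reconstruct("sirt", proj, tiny_op)

    def test_recon_hdf5_round_trip(self, tiny_op, tmp_path):
        rng = np.random.default_rng(3)
        proj = d.ProjectionSet(
            data=rng.random(tiny_op.projection_shape), geometry=tiny_op.geometry
        )
        out = d.sart(proj, tiny_op)
        path = tmp_path / "recon.h5"
        rc.save_recon_hdf5(path, out)
        back = rc.load_recon_hdf5(path)
        np.testing.assert_array_equal(back.data, out.data)
        assert back.algorithm == "sart"
        assert back.params_used == out.params_used
        np.testing.assert_allclose(back.residual_history, out.residual_history)
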