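import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ngfreg import (
    DisplacementField,
    ScalarVolume,
    PathologyMask,
    folding_fraction,
    jacobian_determinant,
    prolong_field,
    restrict_mask,
    restrict_volume,
    warp_image,
)
from ngfreg.transform import (
    gradient_axis,
    gradient_axis_adjoint,
    laplacian_stencil,
    laplacian_stencil_adjoint,
    restrict_field,
    sample_trilinear,
)


def _ramp_x(n, spacing=1.0):
    """Volume whose value equals the world x-coordinate."""
    x = np.arange(n) * spacing
    return ScalarVolume(np.broadcast_to(x[:, None, None], (n, n, n)).copy(),
                        spacing=(spacing,) * 3)


class TestWarpImage:
    def test_zero_field_is_identity(self, rng):
        t = ScalarVolume(rng.standard_normal((8, 8, 8)))
        u = DisplacementField(np.zeros((8, 8, 8, 3)))
        out = warp_image(t, u)
        np.testing.assert_array_equal(out.data, t.data)

    def test_constant_shift_of_linear_ramp(self):
        # T(x) = x0; u = (d, 0, 0) => warped value x0 + d in the interior
        t = _ramp_x(12)
        d = 1.7
        u = DisplacementField(np.zeros((12, 12, 12, 3)))
        u.u[..., 0] = d
        out = warp_image(t, u)
        interior = out.data[2:-4, :, :]
        expected = np.arange(2, 8)[:, None, None] + d
        np.testing.assert_allclose(interior, np.broadcast_to(expected, interior.shape),
                                   atol=1e-12)

    def test_constant_image_invariant_under_any_field(self, rng):
        t = ScalarVolume(np.full((8, 8, 8), 2.5))
        u = DisplacementField(rng.standard_normal((8, 8, 8, 3)) * 3)
        out = warp_image(t, u)
        np.testing.assert_allclose(out.data, 2.5)

    def test_values_bounded_by_input_range(self, rng):
        t = ScalarVolume(rng.standard_normal((10, 10, 10)))
        u = DisplacementField(rng.standard_normal((10, 10, 10, 3)) * 4)
        out = warp_image(t, u)
        assert out.data.min() >= t.data.min() - 1e-12
        assert out.data.max() <= t.data.max() + 1e-12

    def test_grid_mismatch_rejected(self, rng):
        from ngfreg import ngf_distance_gradient, EdgeParameters

        r = ScalarVolume(rng.standard_normal((8, 8, 8)))
        u = DisplacementField(np.zeros((6, 6, 6, 3)))
        with pytest.raises(ValueError):
            ngf_distance_gradient(r, r, u, None, EdgeParameters(0.1, 0.1))


class TestSampleTrilinear:
    def test_exact_at_grid_points(self, rng):
        data = rng.standard_normal((5, 6, 7))
        ijk = np.stack(np.meshgrid(*(np.arange(s, dtype=float) for s in data.shape),
                                   indexing="ij"), axis=-1)
        np.testing.assert_allclose(sample_trilinear(data, ijk), data, atol=1e-14)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_interpolated_value_within_cell_bounds(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((4, 4, 4))
        p = rng.uniform(-1, 4, size=(20, 3))
        vals = sample_trilinear(data, p)
        assert np.all(vals >= data.min() - 1e-12)
        assert np.all(vals <= data.max() + 1e-12)


class TestRestrictProlong:
    def test_restrict_constant(self):
        v = ScalarVolume(np.full((4, 4, 4), 3.0))
        out = restrict_volume(v)
        assert out.shape == (2, 2, 2)
        np.testing.assert_allclose(out.data, 3.0)
        np.testing.assert_allclose(out.spacing, 2.0)

    def test_restrict_block_mean(self):
        v = ScalarVolume(np.arange(8, dtype=float).reshape(2, 2, 2))
        out = restrict_volume(v)
        assert out.shape == (1, 1, 1)
        assert out.data[0, 0, 0] == pytest.approx(3.5)

    def test_restrict_odd_edge_rejected(self):
        with pytest.raises(ValueError):
            restrict_volume(ScalarVolume(np.zeros((5, 5, 5))))

    def test_prolong_zero_field(self):
        u = DisplacementField(np.zeros((4, 4, 4, 3)), spacing=(2, 2, 2),
                              origin=(0.5, 0.5, 0.5))
        out = prolong_field(u, (8, 8, 8), (1, 1, 1), (0, 0, 0))
        assert np.all(out.u == 0)

    def test_prolong_constant_field(self):
        u = DisplacementField(np.zeros((4, 4, 4, 3)), spacing=(2, 2, 2),
                              origin=(0.5, 0.5, 0.5))
        u.u[..., 0] = 3.0
        out = prolong_field(u, (8, 8, 8), (1, 1, 1), (0, 0, 0))
        np.testing.assert_allclose(out.u[..., 0], 3.0)
        np.testing.assert_allclose(out.u[..., 1:], 0.0)

    def test_prolong_linear_field_interior(self):
        # u0(x) = 0.1 * x0 evaluated at finer voxel centers
        n = 6
        x = 0.5 + np.arange(n) * 2.0
        u = DisplacementField(np.zeros((n, n, n, 3)), spacing=(2, 2, 2),
                              origin=(0.5, 0.5, 0.5))
        u.u[..., 0] = np.broadcast_to(0.1 * x[:, None, None], (n, n, n))
        out = prolong_field(u, (12, 12, 12), (1, 1, 1), (0, 0, 0))
        xf = np.arange(12, dtype=float)
        interior = slice(2, -2)
        np.testing.assert_allclose(
            out.u[interior, 6, 6, 0], 0.1 * xf[interior], atol=1e-10)

    def test_restrict_then_prolong_constant_is_identity(self):
        u = DisplacementField(np.zeros((8, 8, 8, 3)))
        u.u[..., 1] = -1.25
        coarse = restrict_field(u)
        back = prolong_field(coarse, u.shape, u.spacing, u.origin)
        np.testing.assert_allclose(back.u, u.u, atol=1e-12)

    def test_prolong_incompatible_extent_rejected(self):
        u = DisplacementField(np.zeros((4, 4, 4, 3)), spacing=(2, 2, 2))
        with pytest.raises(ValueError, match="extent"):
            prolong_field(u, (20, 20, 20), (1, 1, 1), (0, 0, 0))

    def test_mask_restriction_majority_vote(self):
        m = np.zeros((4, 4, 4), dtype=np.uint8)
        m[:2, :2, :2] = 1  # full block -> 1
        m[2, 2, 2] = 1     # 1/8 block -> 0
        out = restrict_mask(PathologyMask(m))
        assert out.data[0, 0, 0] == 1
        assert out.data[1, 1, 1] == 0
        assert set(np.unique(out.data)) <= {0, 1}


class TestJacobian:
    def test_zero_field_gives_unit_determinant(self):
        u = DisplacementField(np.zeros((6, 6, 6, 3)))
        det = jacobian_determinant(u)
        np.testing.assert_allclose(det.data, 1.0, atol=1e-14)
        assert folding_fraction(u) == 0.0

    def test_uniform_scaling_determinant(self):
        # u(x) = 0.1 x => y = 1.1 x => det = 1.1^3 everywhere (affine field,
        # exact for the central/one-sided difference stencils)
        n = 8
        xs = [np.arange(n, dtype=float)] * 3
        X = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
        u = DisplacementField(0.1 * X)
        det = jacobian_determinant(u)
        np.testing.assert_allclose(det.data, 1.1**3, atol=1e-10)

    def test_general_affine_matches_analytic_determinant(self, rng):
        A = rng.standard_normal((3, 3)) * 0.1
        n = 7
        xs = [np.arange(n, dtype=float)] * 3
        X = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
        u = DisplacementField(X @ A.T)
        det = jacobian_determinant(u)
        expected = np.linalg.det(np.eye(3) + A)
        np.testing.assert_allclose(det.data, expected, atol=1e-10)

    def test_constructed_folding_detected(self):
        # strong opposing shift along x folds the map: u0 = -2.5 * x0 gives
        # dy0/dx0 = -1.5 < 0 analytically
        n = 6
        x = np.arange(n, dtype=float)
        u = DisplacementField(np.zeros((n, n, n, 3)))
        u.u[..., 0] = np.broadcast_to(-2.5 * x[:, None, None], (n, n, n))
        det = jacobian_determinant(u)
        np.testing.assert_allclose(det.data, -1.5, atol=1e-10)
        assert folding_fraction(u) == 1.0

    def test_small_smooth_field_is_fold_free(self, rng):
        from scipy.ndimage import gaussian_filter

        u = np.stack([gaussian_filter(rng.standard_normal((10, 10, 10)), 2)
                      for _ in range(3)], axis=-1)
        u *= 0.25 / np.abs(u).max()
        assert folding_fraction(DisplacementField(u)) == 0.0

    def test_folding_fraction_matches_direct_count(self, rng):
        u = DisplacementField(rng.standard_normal((8, 8, 8, 3)) * 2.0)
        det = jacobian_determinant(u).data
        assert folding_fraction(u) == pytest.approx(np.mean(det <= 0))


class TestStencils:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(0, 2))
    def test_gradient_adjoint_identity(self, seed, axis):
        # <D f, w> == <f, D^T w> for the central/one-sided stencil
        rng = np.random.default_rng(seed)
        f = rng.standard_normal((6, 7, 8))
        w = rng.standard_normal((6, 7, 8))
        h = float(rng.uniform(0.5, 2.0))
        lhs = np.sum(gradient_axis(f, axis, h) * w)
        rhs = np.sum(f * gradient_axis_adjoint(w, axis, h))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_laplacian_adjoint_identity(self, rng):
        f = rng.standard_normal((6, 6, 6))
        w = rng.standard_normal((6, 6, 6))
        sp = np.array([1.0, 1.3, 0.8])
        lhs = np.sum(laplacian_stencil(f, sp) * w)
        rhs = np.sum(f * laplacian_stencil_adjoint(w, sp))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_laplacian_annihilates_affine(self, rng):
        A = rng.standard_normal((3, 3))
        n = 6
        X = np.stack(np.meshgrid(*[np.arange(n, dtype=float)] * 3, indexing="ij"),
                     axis=-1)
        f = X @ A[0] + 2.0
        np.testing.assert_allclose(laplacian_stencil(f, np.ones(3)), 0.0, atol=1e-12)

    def test_gradient_of_ramp(self):
        v = _ramp_x(8, spacing=0.5)
        g = gradient_axis(v.data, 0, 0.5)
        np.testing.assert_allclose(g, 1.0, atol=1e-12)
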