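"""Decomposition, projection and reconstruction of RGB image stacks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flfsi import rgb2dpca
from flfsi.rgb2dpca import ShapeError


def _rand_stack(rng, n, h, w):
    return rgb2dpca.as_stack(rng.uniform(0.0, 1.0, size=(n, h, w, 3)))


class TestMeanImage:
    def test_single_image_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(4, 5, 3))
        np.testing.assert_array_equal(rgb2dpca.compute_mean_image([img]), img)

    def test_two_constant_images(self):
        a = np.zeros((3, 3, 3))
        b = np.full((3, 3, 3), 2.0)
        np.testing.assert_allclose(
            rgb2dpca.compute_mean_image([a, b]), np.ones((3, 3, 3))
        )

    def test_matches_accumulation_loop(self):
        rng = np.random.default_rng(1)
        stack = _rand_stack(rng, 5, 4, 4)
        acc = np.zeros((4, 4, 3))
        for img in stack:  # brute-force accumulation oracle
            acc = acc + img
        np.testing.assert_allclose(
            rgb2dpca.compute_mean_image(stack), acc / 5, atol=1e-12
        )

    def test_empty_stack_rejected(self):
        with pytest.raises(ShapeError, match="empty stack"):
            rgb2dpca.compute_mean_image([])

    def test_shape_mismatch_names_offender(self):
        rng = np.random.default_rng(2)
        imgs = [rng.uniform(size=(4, 4, 3)), rng.uniform(size=(4, 5, 3))]
        with pytest.raises(ShapeError, match="stack image 1"):
            rgb2dpca.compute_mean_image(imgs)


class TestCovariance:
    def test_identical_images_give_zero(self):
        img = np.random.default_rng(3).uniform(size=(5, 4, 3))
        cov = rgb2dpca.compute_covariance([img, img, img])
        np.testing.assert_allclose(cov, 0.0, atol=1e-14)

    def test_hand_checkable_2x2(self):
        # centered values are +/- [[1,0],[0,0]] per channel
        a = np.zeros((2, 2, 3))
        b = np.zeros((2, 2, 3))
        a[0, 0, :] = 2.0
        cov = rgb2dpca.compute_covariance([a, b])
        expected = np.array([[1.0, 0.0], [0.0, 0.0]])
        for c in range(3):
            np.testing.assert_allclose(cov[:, :, c], expected, atol=1e-14)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        stack = _rand_stack(rng, 6, 5, 4)
        mean = stack.mean(axis=0)
        cov = rgb2dpca.compute_covariance(stack)
        for c in range(3):
            naive = np.zeros((4, 4))
            for i in range(6):
                diff = stack[i, :, :, c] - mean[:, :, c]
                naive += diff.T @ diff
            naive /= 6
            np.testing.assert_allclose(cov[:, :, c], naive, atol=1e-10)

    def test_symmetric_psd(self):
        rng = np.random.default_rng(5)
        cov = rgb2dpca.compute_covariance(_rand_stack(rng, 4, 6, 5))
        for c in range(3):
            m = cov[:, :, c]
            np.testing.assert_allclose(m, m.T, atol=1e-9)
            eig = np.linalg.eigvalsh(m)
            assert eig.min() >= -1e-8 * max(eig.max(), 1e-30)

    def test_mean_shape_mismatch(self):
        rng = np.random.default_rng(6)
        stack = _rand_stack(rng, 3, 4, 4)
        with pytest.raises(ShapeError):
            rgb2dpca.compute_covariance(stack, mean=np.zeros((5, 4, 3)))


class TestEigendecompose:
    def test_identity_covariance(self):
        cov = np.repeat(np.eye(3)[:, :, None], 3, axis=2)
        basis = rgb2dpca.eigendecompose(cov)
        np.testing.assert_allclose(basis.values, 1.0)
        for c in range(3):
            v = basis.vectors[:, :, c]
            np.testing.assert_allclose(v.T @ v, np.eye(3), atol=1e-8)
            for j in range(3):
                col = v[:, j]
                assert col[np.nonzero(np.abs(col) > 1e-12)[0][0]] >= 0

    def test_diagonal_covariance(self):
        cov = np.repeat(np.diag([3.0, 1.0])[:, :, None], 3, axis=2)
        basis = rgb2dpca.eigendecompose(cov)
        np.testing.assert_allclose(basis.values[:, 0], [3.0, 1.0])
        np.testing.assert_allclose(np.abs(basis.vectors[:, :, 0]), np.eye(2), atol=1e-12)

    def test_residual_and_characteristic_polynomial(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(4, 4))
        sym = a @ a.T  # PSD
        cov = np.repeat(sym[:, :, None], 3, axis=2)
        basis = rgb2dpca.eigendecompose(cov)
        lam, vec = basis.values[:, 0], basis.vectors[:, :, 0]
        for j in range(4):
            assert np.linalg.norm(sym @ vec[:, j] - lam[j] * vec[:, j]) < 1e-8
        # independent oracle: roots of the characteristic polynomial
        roots = np.sort(np.roots(np.poly(sym)).real)[::-1]
        np.testing.assert_allclose(lam, roots, rtol=1e-8, atol=1e-8)

    def test_eigenvalue_trace_identity(self, phantom_ds):
        cov = rgb2dpca.compute_covariance(phantom_ds.conv)
        basis = rgb2dpca.eigendecompose(cov)
        for c in range(3):
            trace = np.trace(cov[:, :, c])
            assert abs(basis.values[:, c].sum() - trace) <= 1e-8 * abs(trace)

    def test_covariance_reassembly(self, phantom_ds):
        cov = rgb2dpca.compute_covariance(phantom_ds.conv)
        basis = rgb2dpca.eigendecompose(cov)
        for c in range(3):
            v, lam = basis.vectors[:, :, c], basis.values[:, c]
            rebuilt = v @ np.diag(lam) @ v.T
            rel = np.linalg.norm(rebuilt - cov[:, :, c]) / np.linalg.norm(cov[:, :, c])
            assert rel < 1e-6

    def test_nonsymmetric_rejected(self):
        cov = np.zeros((3, 3, 3))
        cov[0, 1, :] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            rgb2dpca.eigendecompose(cov)

    def test_sign_convention_deterministic(self, phantom_ds):
        cov = rgb2dpca.compute_covariance(phantom_ds.conv)
        b1 = rgb2dpca.eigendecompose(cov)
        b2 = rgb2dpca.eigendecompose(cov.copy())
        np.testing.assert_array_equal(b1.vectors, b2.vectors)


class TestProjectReconstruct:
    def test_identity_basis_projection(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(size=(4, 3, 3))
        eye = np.repeat(np.eye(3)[:, :, None], 3, axis=2)
        basis = rgb2dpca.ProjectionBasis(vectors=eye, values=np.ones((3, 3)))
        np.testing.assert_allclose(rgb2dpca.project(img, basis), img)

    def test_hand_projection_2x2(self):
        img = np.repeat(np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None], 3, axis=2)
        w = np.array([[1, 1], [1, -1]]) / np.sqrt(2)
        basis = rgb2dpca.ProjectionBasis(
            vectors=np.repeat(w[:, :, None], 3, axis=2), values=np.ones((2, 3))
        )
        proj = rgb2dpca.project(img, basis)
        expected = np.array([[3, -1], [7, -1]]) / np.sqrt(2)
        for c in range(3):
            np.testing.assert_allclose(proj[:, :, c], expected, atol=1e-12)

    def test_projection_matches_column_loop(self, phantom_ds, phantom_basis):
        img = phantom_ds.conv[0]
        proj = rgb2dpca.project(img, phantom_basis)
        for c in range(3):
            for j in range(phantom_basis.dim):
                oracle = img[:, :, c] @ phantom_basis.vectors[:, j, c]
                np.testing.assert_allclose(proj[:, j, c], oracle, atol=1e-12)

    def test_full_mask_completeness(self, phantom_ds, phantom_basis):
        d = phantom_basis.dim
        for img in phantom_ds.conv[:3]:
            proj = rgb2dpca.project(img, phantom_basis)
            recon = rgb2dpca.reconstruct(proj, phantom_basis, np.ones((d, 3), np.uint8))
            per_channel, _ = rgb2dpca.frobenius_error(img, recon)
            norms, _ = rgb2dpca.frobenius_error(img, np.zeros_like(img))
            assert (per_channel / norms < 1e-8).all()

    def test_zero_mask_gives_zero_image(self, phantom_ds, phantom_basis):
        proj = rgb2dpca.project(phantom_ds.conv[0], phantom_basis)
        recon = rgb2dpca.reconstruct(
            proj, phantom_basis, np.zeros((phantom_basis.dim, 3), np.uint8)
        )
        np.testing.assert_array_equal(recon, 0.0)

    def test_single_component_is_outer_product(self, phantom_ds, phantom_basis):
        img = phantom_ds.conv[1]
        proj = rgb2dpca.project(img, phantom_basis)
        mask = np.zeros((phantom_basis.dim, 3), np.uint8)
        j = 2
        mask[j, :] = 1
        recon = rgb2dpca.reconstruct(proj, phantom_basis, mask)
        for c in range(3):
            oracle = np.outer(proj[:, j, c], phantom_basis.vectors[:, j, c])
            np.testing.assert_allclose(recon[:, :, c], oracle, atol=1e-12)

    def test_topk_error_monotone_in_k(self, phantom_ds, phantom_basis):
        d = phantom_basis.dim
        for img in phantom_ds.conv[:2]:
            proj = rgb2dpca.project(img, phantom_basis)
            prev = np.full(3, np.inf)
            for k in range(1, d + 1):
                recon = rgb2dpca.reconstruct(proj, phantom_basis, rgb2dpca.topk_mask(d, k))
                per_channel, _ = rgb2dpca.frobenius_error(img, recon)
                assert (per_channel <= prev + 1e-10).all()
                prev = per_channel

    def test_width_mismatch_rejected(self, phantom_basis):
        with pytest.raises(ShapeError, match="width"):
            rgb2dpca.project(np.zeros((4, 5, 3)), phantom_basis)

    def test_centered_reconstruction_roundtrip(self, phantom_ds, phantom_basis):
        mean = phantom_ds.conv.mean(axis=0)
        img = phantom_ds.conv[0]
        full = np.ones((phantom_basis.dim, 3), np.uint8)
        recon = rgb2dpca.reconstruct_image(
            img, phantom_basis, full, centered_reconstruction=True, mean=mean
        )
        np.testing.assert_allclose(recon, img, atol=1e-8)


class TestFrobeniusError:
    def test_identical_inputs(self):
        img = np.random.default_rng(9).uniform(size=(3, 3, 3))
        per_channel, total = rgb2dpca.frobenius_error(img, img)
        np.testing.assert_array_equal(per_channel, 0.0)
        assert total == 0.0

    def test_three_four_five(self):
        x = np.zeros((2, 2, 3))
        x[0, 0, 0], x[0, 1, 0] = 3.0, 4.0
        per_channel, total = rgb2dpca.frobenius_error(x, np.zeros_like(x))
        assert per_channel[0] == pytest.approx(5.0)
        assert total == pytest.approx(5.0)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(10)
        x, y = rng.uniform(size=(4, 5, 3)), rng.uniform(size=(4, 5, 3))
        per_channel, _ = rgb2dpca.frobenius_error(x, y)
        for c in range(3):
            acc = 0.0
            for i in range(4):
                for j in range(5):
                    acc += (x[i, j, c] - y[i, j, c]) ** 2
            assert per_channel[c] == pytest.approx(np.sqrt(acc), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            rgb2dpca.frobenius_error(np.zeros((2, 2, 3)), np.zeros((2, 3, 3)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_completeness_identity_property(seed):
    """Any image reconstructs exactly from its full orthonormal basis."""
    rng = np.random.default_rng(seed)
    stack = rgb2dpca.as_stack(rng.uniform(0.05, 1.0, size=(3, 5, 4, 3)))
    basis = rgb2dpca.fit_basis(stack)
    img = stack[0]
    recon = rgb2dpca.reconstruct(
        rgb2dpca.project(img, basis), basis, np.ones((4, 3), np.uint8)
    )
    per_channel, _ = rgb2dpca.frobenius_error(img, recon)
    norms, _ = rgb2dpca.frobenius_error(img, np.zeros_like(img))
    assert (per_channel < 1e-8 * np.maximum(norms, 1e-12)).all()


class TestImageIO:
    def test_png_roundtrip_8bit(self, tmp_path):
        rng = np.random.default_rng(11)
        img = rng.uniform(size=(8, 8, 3))
        path = tmp_path / "img.png"
        rgb2dpca.save_image(path, img)
        loaded = rgb2dpca.load_image(path)
        assert np.abs(loaded - img).max() <= 0.5 / 255 + 1e-9

    def test_tiff_roundtrip_float(self, tmp_path):
        img = np.random.default_rng(12).uniform(size=(6, 6, 3))
        path = tmp_path / "img.tif"
        rgb2dpca.save_image(path, img)
        loaded = rgb2dpca.load_image(path)
        np.testing.assert_allclose(loaded, img.astype(np.float32), atol=1e-7)

    def test_grayscale_replicated_with_warning(self, tmp_path, caplog):
        import imageio.v3 as iio

        path = tmp_path / "gray.png"
        iio.imwrite(path, np.full((8, 8), 128, dtype=np.uint8))
        with caplog.at_level("WARNING", logger="flfsi"):
            img = rgb2dpca.load_image(path)
        assert img.shape == (8, 8, 3)
        np.testing.assert_array_equal(img[:, :, 0], img[:, :, 2])
        assert "grayscale" in caplog.text

    def test_stack_order_is_lexicographic(self, tmp_path):
        rng = np.random.default_rng(13)
        for name in ("b.png", "a.png", "c.png"):
            rgb2dpca.save_image(tmp_path / name, rng.uniform(size=(4, 4, 3)))
        _, names = rgb2dpca.load_stack(tmp_path)
        assert names == ["a.png", "b.png", "c.png"]

    def test_missing_directory(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            rgb2dpca.load_stack(tmp_path / "nope")
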