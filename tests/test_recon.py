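"""Scattered-slice reconstruction, adjoint correctness, SH fitting."""

import numpy as np
import pytest

from slicedwi import recon
from slicedwi.interp import trilinear_gather, trilinear_scatter
from slicedwi.recon import (forward_project, n_sh_coeffs, real_sh_basis,
                            reconstruct_sh, reconstruct_volume, reorient_bvec)
from slicedwi.transforms import RigidTransform

VOX = (2.0, 2.0, 2.0)


@pytest.fixture(scope="module")
def volume():
    rng = np.random.default_rng(0)
    from scipy.ndimage import gaussian_filter
    v = gaussian_filter(rng.random((16, 16, 10)), 1.2)
    v[:2] = v[-2:] = 0.0
    return v


class TestForwardProject:
    def test_delta_profile_extracts_plane(self, volume):
        out = forward_project(volume, RigidTransform.identity(), 5,
                              voxel_size=VOX, profile="delta")
        np.testing.assert_allclose(out, volume[:, :, 4], atol=1e-12)

    def test_translation_by_one_thickness_gives_adjacent_plane(self, volume):
        T = RigidTransform.from_translation([0, 0, VOX[2]])
        out = forward_project(volume, T, 5, voxel_size=VOX, profile="delta")
        np.testing.assert_allclose(out, volume[:, :, 5], atol=1e-12)

    def test_gaussian_profile_matches_1d_convolution(self):
        """A through-plane step edge blurs exactly like the 1-D discrete
        slice-profile kernel applied to the z-profile."""
        step = np.zeros((8, 8, 12))
        step[:, :, 6:] = 1.0
        from slicedwi.recon import _profile_taps
        offsets, w = _profile_taps(VOX[2], VOX, "gaussian", 3)
        z_slice = 6
        out = forward_project(step, RigidTransform.identity(), z_slice,
                              voxel_size=VOX, slice_thickness=VOX[2])
        prof = step[0, 0, :]
        zq = (z_slice - 1) + offsets / VOX[2]
        expected = sum(wk * np.interp(q, np.arange(12), prof)
                       for wk, q in zip(w, zq))
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestAdjoint:
    def test_gather_scatter_adjoint(self):
        """<A x, y> == <x, A^T y> for the trilinear sampling pair."""
        rng = np.random.default_rng(1)
        shape = (9, 8, 7)
        for _ in range(20):
            x = rng.standard_normal(shape)
            coords = rng.uniform(-1, 9, size=(3, 40))
            y = rng.standard_normal(40)
            lhs = np.dot(trilinear_gather(x, coords), y)
            rhs = np.vdot(x, trilinear_scatter(y, coords, shape))
            assert abs(lhs - rhs) < 1e-8 * max(abs(lhs), 1.0)

    def test_slice_operator_adjoint(self, volume):
        rng = np.random.default_rng(2)
        from slicedwi.recon import _SliceStackOperator
        T = RigidTransform.from_params([0.5, -1.0, 0.3, 2.0, -1.0, 3.0])
        op = _SliceStackOperator(volume.shape, VOX, [5], [T], VOX[2])
        x = rng.standard_normal(volume.shape)
        y = rng.standard_normal(op.npix)
        lhs = np.dot(op.forward_one(x, 0), y)
        rhs = np.vdot(x, op.adjoint_one(y, 0))
        assert abs(lhs - rhs) < 1e-8 * max(abs(lhs), 1.0)


class TestReconstructVolume:
    def _stack(self, volume, transform=RigidTransform.identity()):
        zs = list(range(1, volume.shape[2] + 1))
        slices = [forward_project(volume, transform, z, voxel_size=VOX,
                                  profile="delta") for z in zs]
        return slices, zs

    def test_consistent_data_recovered(self, volume):
        slices, zs = self._stack(volume)
        out = reconstruct_volume(slices * 2,
                                 [RigidTransform.identity()] * (2 * len(zs)),
                                 np.ones(2 * len(zs)), voxel_size=VOX,
                                 zs=zs * 2, profile="delta",
                                 lambda_reg=1e-4, max_iter=50)
        rms = np.sqrt(np.mean((out - volume) ** 2))
        assert rms < 0.01 * np.abs(volume).max()

    def test_shifted_copies_inverted(self, volume):
        T = RigidTransform.from_translation([0, 2.0, 0])
        shifted = [forward_project(volume, T, z, voxel_size=VOX,
                                   profile="delta")
                   for z in range(1, volume.shape[2] + 1)]
        plain, zs = self._stack(volume)
        out = reconstruct_volume(
            plain + shifted,
            [RigidTransform.identity()] * len(zs) + [T] * len(zs),
            np.ones(2 * len(zs)), voxel_size=VOX, zs=zs * 2,
            profile="delta", lambda_reg=1e-4, max_iter=50)
        inner = (slice(2, -2),) * 3
        rms = np.sqrt(np.mean((out - volume)[inner] ** 2))
        assert rms < 0.015 * np.abs(volume).max()

    def test_strong_regularization_flattens(self, volume):
        slices, zs = self._stack(volume)
        out = reconstruct_volume(slices, [RigidTransform.identity()] * len(zs),
                                 np.ones(len(zs)), voxel_size=VOX, zs=zs,
                                 profile="delta", lambda_reg=1e6, max_iter=100)
        grad = np.concatenate([np.abs(np.diff(out, axis=a)).ravel()
                               for a in range(3)])
        assert grad.max() < 1e-3 * np.abs(volume).max()

    def test_objective_non_increasing(self, volume):
        slices, zs = self._stack(volume)
        _, info = reconstruct_volume(slices,
                                     [RigidTransform.identity()] * len(zs),
                                     np.ones(len(zs)), voxel_size=VOX, zs=zs,
                                     return_info=True)
        obj = np.array(info["objective"])
        assert np.all(np.diff(obj) <= 1e-9 * np.abs(obj[0]))

    def test_weighted_average_oracle(self, volume):
        """Identity transforms, delta profile, no regularization: the normal
        equations reduce to the per-voxel weighted average of the stacks."""
        noisy1 = volume + 0.1
        noisy2 = volume - 0.05
        zs = list(range(1, volume.shape[2] + 1))
        slices = [noisy1[:, :, z - 1] for z in zs] + \
                 [noisy2[:, :, z - 1] for z in zs]
        w = [3.0] * len(zs) + [1.0] * len(zs)
        out = reconstruct_volume(slices,
                                 [RigidTransform.identity()] * (2 * len(zs)),
                                 w, voxel_size=VOX, zs=zs * 2, profile="delta",
                                 lambda_reg=0.0, max_iter=80, tol=1e-10)
        oracle = (3 * noisy1 + 1 * noisy2) / 4
        np.testing.assert_allclose(out, oracle, atol=1e-5)


class TestReorient:
    def test_identity(self):
        g = np.array([0.0, 1.0, 0.0])
        np.testing.assert_allclose(reorient_bvec(g, RigidTransform.identity()), g)

    def test_quarter_turn(self):
        T = RigidTransform.from_params([0, 0, 0, 0, 0, 90.0])
        np.testing.assert_allclose(reorient_bvec([1.0, 0, 0], T), [0, 1.0, 0],
                                   atol=1e-12)

    def test_norm_preserved(self):
        rng = np.random.default_rng(3)
        from scipy.spatial.transform import Rotation
        for _ in range(1000):
            m = np.eye(4)
            m[:3, :3] = Rotation.random(random_state=rng).as_matrix()
            g = rng.standard_normal(3)
            g /= np.linalg.norm(g)
            out = reorient_bvec(g, RigidTransform(m))
            assert abs(np.linalg.norm(out) - 1.0) < 1e-12


class TestShBasis:
    def test_closed_form_low_orders(self):
        """l=0 and the l=2, m=0 harmonic match their closed forms."""
        dirs = np.array([[0, 0, 1.0], [1.0, 0, 0],
                         [0.6, 0.48, np.sqrt(1 - 0.6**2 - 0.48**2)]])
        Y = real_sh_basis(4, dirs)
        np.testing.assert_allclose(Y[:, 0], 1 / np.sqrt(4 * np.pi), atol=1e-12)
        z = dirs[:, 2]
        y20 = np.sqrt(5 / (16 * np.pi)) * (3 * z**2 - 1)
        np.testing.assert_allclose(Y[:, 3], y20, atol=1e-12)

    def test_orthonormal_under_quadrature(self):
        """Random-direction Monte-Carlo Gram matrix approaches identity."""
        rng = np.random.default_rng(4)
        v = rng.standard_normal((60000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        Y = real_sh_basis(4, v)
        gram = (Y.T @ Y) / len(v) * 4 * np.pi
        np.testing.assert_allclose(gram, np.eye(n_sh_coeffs(4)), atol=0.05)

    def test_antipodal_symmetry(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal((50, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        np.testing.assert_allclose(real_sh_basis(4, v), real_sh_basis(4, -v),
                                   atol=1e-12)


class TestReconstructSh:
    def _directions(self, n, seed=6):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal((n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    def test_isotropic_signal_is_l0_only(self):
        shape = (8, 8, 6)
        base = np.zeros(shape)
        base[2:6, 2:6, 1:5] = 1.0
        dirs = self._directions(20)
        zs, slices, gvecs, trs = [], [], [], []
        for z in range(1, 7):
            for g in dirs[:8]:
                zs.append(z)
                slices.append(base[:, :, z - 1])
                gvecs.append(g)
                trs.append(RigidTransform.identity())
        sh = reconstruct_sh(slices, trs, np.ones(len(slices)), gvecs,
                            l_max=2, b_value=1000.0, voxel_size=VOX, zs=zs,
                            profile="delta", lambda_reg=1e-4, max_iter=60)
        c0 = sh.coeffs[..., 0]
        rest = np.abs(sh.coeffs[..., 1:]).max()
        assert rest < 1e-3 * np.abs(c0).max()

    def test_synthetic_sh_field_recovered(self):
        """Order-4 SH coefficients forward-simulated with known rotations are
        recovered with coefficient correlation > 0.99."""
        rng = np.random.default_rng(7)
        shape = (8, 8, 6)
        ncoef = n_sh_coeffs(4)
        truth = np.zeros(shape + (ncoef,))
        blob = np.zeros(shape)
        blob[2:6, 2:6, 1:5] = 1.0
        truth[..., 0] = blob
        truth[..., 1:] = blob[..., None] * 0.3 * rng.standard_normal(ncoef - 1)
        from scipy.spatial.transform import Rotation
        dirs = self._directions(40, seed=8)
        zs, slices, gvecs, trs = [], [], [], []
        k = 0
        for z in range(1, 7):
            for _ in range(20):
                g = dirs[k % len(dirs)]
                k += 1
                ang = rng.uniform(-10, 10)
                m = np.eye(4)
                m[:3, :3] = Rotation.from_euler("z", ang, degrees=True).as_matrix()
                T = RigidTransform(m)
                Yrow = real_sh_basis(4, reorient_bvec(g, T))[0]
                slices.append(forward_project(truth @ Yrow, T, z,
                                              voxel_size=VOX, profile="delta"))
                zs.append(z)
                gvecs.append(g)
                trs.append(T)
        sh = reconstruct_sh(slices, trs, np.ones(len(slices)), gvecs,
                            l_max=4, b_value=1000.0, voxel_size=VOX, zs=zs,
                            profile="delta", lambda_reg=1e-5, max_iter=250)
        sel = blob > 0
        r = np.corrcoef(sh.coeffs[sel].ravel(), truth[sel].ravel())[0, 1]
        assert r > 0.99

    def test_antipodal_pairs_equivalent(self):
        shape = (8, 8, 4)
        blob = np.zeros(shape)
        blob[2:6, 2:6, 1:3] = 1.0
        dirs = self._directions(8, seed=9)
        zs = [z for z in range(1, 5) for _ in range(8)]
        slices = [blob[:, :, (z - 1) % 4] for z in zs]
        trs = [RigidTransform.identity()] * len(zs)
        gv = [dirs[i % 8] for i in range(len(zs))]
        a = reconstruct_sh(slices, trs, np.ones(len(zs)), gv, l_max=2,
                           b_value=1000.0, voxel_size=VOX, zs=zs,
                           profile="delta", max_iter=40)
        b = reconstruct_sh(slices, trs, np.ones(len(zs)),
                           [-g for g in gv], l_max=2, b_value=1000.0,
                           voxel_size=VOX, zs=zs, profile="delta", max_iter=40)
        np.testing.assert_allclose(a.coeffs, b.coeffs, atol=1e-10)

    def test_underdetermined_shell_rejected(self):
        shape = (8, 8, 4)
        blob = np.ones(shape)
        dirs = self._directions(3, seed=10)
        zs = [1, 2, 3]
        with pytest.raises(ValueError, match="l_max"):
            reconstruct_sh([blob[:, :, z - 1] for z in zs],
                           [RigidTransform.identity()] * 3, np.ones(3),
                           list(dirs), l_max=4, b_value=1000.0,
                           voxel_size=VOX, zs=zs)
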