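"""Scattered-slice least-squares reconstruction and SH fitting.

Motion-corrected slices are scattered in space: each 2-D slice observes the
underlying volume through a rigid transform and a through-plane Gaussian
slice profile (FWHM = slice thickness).  The volume (or, per shell, a
per-voxel vector of real even-order spherical-harmonic coefficients) is
recovered by conjugate gradient on the normal equations of

    min_x  sum_t w_t || P_t x - y_t ||^2  +  lambda || grad x ||^2,

where P_t is the slice-sampling forward model.  Sampling and its adjoint use
an exactly matched gather/scatter pair, so the normal operator is symmetric
positive semi-definite and CG converges monotonically.  Gradient
reorientation of the b-vectors under each slice's rotation is applied before
evaluating the SH basis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from .interp import slice_world_coords, trilinear_gather, trilinear_scatter, world_to_voxel
from .transforms import RigidTransform

__all__ = [
    "SHCoefficientVolume",
    "forward_project",
    "reconstruct_volume",
    "reorient_bvec",
    "reconstruct_sh",
    "real_sh_basis",
    "n_sh_coeffs",
]

log = logging.getLogger(__name__)


def _profile_taps(slice_thickness: float, voxel_size, profile: str = "gaussian",
                  n_taps: int = 3):
    """Through-plane sample offsets (mm) and weights of the slice profile."""
    if profile == "delta":
        return np.array([0.0]), np.array([1.0])
    sigma = slice_thickness / 2.355  # FWHM -> sigma
    offsets = np.linspace(-1.2 * sigma, 1.2 * sigma, n_taps)
    w = np.exp(-0.5 * (offsets / sigma) ** 2)
    return offsets, w / w.sum()


def _slice_sample_coords(shape, voxel_size, z: int, transform: RigidTransform,
                         offsets):
    """Voxel coordinates of all profile taps for one slice: (K, 3, npix)."""
    X = slice_world_coords(shape, voxel_size, z)
    coords = []
    for o in offsets:
        Xo = X.copy()
        Xo[2] += o
        coords.append(world_to_voxel(transform.apply(Xo), shape, voxel_size))
    return coords


def forward_project(volume: np.ndarray, transform: RigidTransform, z: int,
                    voxel_size=(2.2, 2.2, 2.2), slice_thickness: float | None = None,
                    profile: str = "gaussian", n_taps: int = 3) -> np.ndarray:
    """Resample the transformed volume at geometric slice ``z`` (1-based),
    convolved through-plane with the slice profile."""
    volume = np.asarray(volume, dtype=float)
    if slice_thickness is None:
        slice_thickness = voxel_size[2]
    offsets, w = _profile_taps(slice_thickness, voxel_size, profile, n_taps)
    coords = _slice_sample_coords(volume.shape, voxel_size, z, transform, offsets)
    nx, ny = volume.shape[0], volume.shape[1]
    out = np.zeros(nx * ny)
    for wk, ck in zip(w, coords):
        out += wk * trilinear_gather(volume, ck)
    return out.reshape(nx, ny)


def _grad_sq_adjoint(x: np.ndarray) -> np.ndarray:
    """G^T G x for the forward-difference gradient (negative Laplacian)."""
    out = np.zeros_like(x)
    for ax in range(x.ndim):
        g = np.diff(x, axis=ax)
        lo = [slice(None)] * x.ndim
        hi = [slice(None)] * x.ndim
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        out[tuple(lo)] -= g
        out[tuple(hi)] += g
    return out


def _cg(hess, b, x0, max_iter, tol):
    """Conjugate gradient for SPD ``hess``; returns (x, objective trace)."""
    x = x0.copy()
    r = b - hess(x)
    p = r.copy()
    rs = float(np.vdot(r, r))
    b_norm = max(float(np.linalg.norm(b)), 1e-30)
    # Phi(x) = 1/2 x^T H x - b^T x, tracked by the CG recurrence
    obj = [float(-0.5 * np.vdot(x, r) - 0.5 * np.vdot(x, b))]
    for _ in range(max_iter):
        hp = hess(p)
        denom = float(np.vdot(p, hp))
        if denom <= 0:
            break
        alpha = rs / denom
        x += alpha * p
        r -= alpha * hp
        obj.append(obj[-1] - 0.5 * alpha * rs)
        rs_new = float(np.vdot(r, r))
        if np.sqrt(rs_new) / b_norm < tol:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x, obj


class _SliceStackOperator:
    """Forward/adjoint slice sampling for a fixed set of slices."""

    def __init__(self, shape, voxel_size, zs, transforms, slice_thickness,
                 profile="gaussian", n_taps=3):
        self.shape = tuple(shape)
        offsets, self.tap_w = _profile_taps(slice_thickness, voxel_size,
                                            profile, n_taps)
        self.coords = [
            _slice_sample_coords(self.shape, voxel_size, z, T, offsets)
            for z, T in zip(zs, transforms)
        ]
        self.npix = self.shape[0] * self.shape[1]

    def forward_one(self, x, i):
        out = np.zeros(self.npix)
        for wk, ck in zip(self.tap_w, self.coords[i]):
            out += wk * trilinear_gather(x, ck)
        return out

    def adjoint_one(self, values, i):
        out = np.zeros(self.shape)
        for wk, ck in zip(self.tap_w, self.coords[i]):
            out += wk * trilinear_scatter(values, ck, self.shape)
        return out

    def __len__(self):
        return len(self.coords)


def reconstruct_volume(slices, transforms, weights, voxel_size=(2.2, 2.2, 2.2),
                       zs=None, slice_thickness: float | None = None,
                       lambda_reg: float | None = None, shape=None,
                       profile: str = "gaussian", n_taps: int = 3,
                       max_iter: int = 30, tol: float = 1e-6,
                       return_info: bool = False):
    """Least-squares scattered-slice reconstruction by conjugate gradient.

    ``slices[i]`` is a 2-D image observed at geometric location ``zs[i]``
    under rigid transform ``transforms[i]`` with weight ``weights[i]``.
    ``lambda_reg`` is the gradient (Tikhonov) penalty weight; the default is
    0.01, relative because both terms are quadratic in intensity.  Voxels
    touched by no slice are filled by the regularizer and counted in the log.
    """
    slices = [np.asarray(s, dtype=float) for s in slices]
    if zs is None:
        raise ValueError("zs (geometric slice locations) required")
    nx, ny = slices[0].shape
    if shape is None:
        shape = (nx, ny, int(max(zs)))
    if slice_thickness is None:
        slice_thickness = voxel_size[2]
    if lambda_reg is None:
        lambda_reg = 0.01
    w = np.asarray(weights, dtype=float)
    if np.all(w == 0):
        raise ValueError("all slice weights are zero")
    # normalize so the data term is O(1) against lambda regardless of the
    # absolute weight scale (weights are often small mask fractions)
    w = w / np.mean(w[w > 0])
    op = _SliceStackOperator(shape, voxel_size, zs, transforms,
                             slice_thickness, profile, n_taps)

    b = np.zeros(shape)
    coverage = np.zeros(shape)
    for i, s in enumerate(slices):
        if w[i] == 0:
            continue
        b += w[i] * op.adjoint_one(s.ravel(), i)
        coverage += w[i] * op.adjoint_one(np.ones(op.npix), i)
    uncovered = int(np.sum(coverage == 0))
    if uncovered:
        log.info("reconstruct_volume: %d voxels uncovered, filled by "
                 "regularization", uncovered)

    def hess(x):
        out = lambda_reg * _grad_sq_adjoint(x)
        for i in range(len(op)):
            if w[i] == 0:
                continue
            out += w[i] * op.adjoint_one(op.forward_one(x, i), i)
        return out

    x0 = b / np.maximum(coverage, 1e-3 * coverage.max() if coverage.max() > 0 else 1.0)
    x, obj = _cg(hess, b, x0, max_iter, tol)
    if return_info:
        return x, {"objective": obj, "uncovered": uncovered,
                   "covered": coverage > 0}
    return x


def reorient_bvec(g, transform: RigidTransform) -> np.ndarray:
    """Rotate a diffusion gradient direction by the transform's rotation."""
    g = np.asarray(g, dtype=float)
    return transform.rotation @ g


def n_sh_coeffs(l_max: int) -> int:
    """Number of real even-order SH coefficients up to ``l_max``."""
    return (l_max + 1) * (l_max + 2) // 2


def real_sh_basis(l_max: int, dirs: np.ndarray) -> np.ndarray:
    """Real, even-order, orthonormal spherical-harmonic basis.

    ``dirs`` is (n, 3) unit vectors; returns (n, n_sh_coeffs(l_max)).
    Ordering is (l, m) with l = 0, 2, ..., l_max and m = -l..l.  For m != 0
    the real harmonics are sqrt(2) times the imaginary (m < 0) or real
    (m > 0) part of the complex harmonic of order |m|, keeping the basis
    orthonormal over the sphere; only even l appear, matching the antipodal
    symmetry of the diffusion signal.
    """
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    norms = np.linalg.norm(dirs, axis=1)
    theta = np.arccos(np.clip(dirs[:, 2] / np.maximum(norms, 1e-12), -1, 1))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    cols = []
    for l in range(0, l_max + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2) * (-1) ** m * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2) * (-1) ** m * y.real)
    return np.stack(cols, axis=1)


@dataclass(frozen=True)
class SHCoefficientVolume:
    """Per-voxel real even-order SH coefficients for one shell."""

    coeffs: np.ndarray  # (nx, ny, nz, ncoef)
    b_value: float
    l_max: int
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        if self.coeffs.shape[-1] != n_sh_coeffs(self.l_max):
            raise ValueError("coefficient count does not match l_max")


def reconstruct_sh(slices, transforms, weights, gvecs, l_max: int,
                   b_value: float, voxel_size=(2.2, 2.2, 2.2), zs=None,
                   shape=None, slice_thickness: float | None = None,
                   lambda_reg: float | None = None, profile: str = "gaussian",
                   n_taps: int = 3, max_iter: int = 40, tol: float = 1e-6,
                   ) -> SHCoefficientVolume:
    """Joint scattered-slice + SH reconstruction of one shell.

    Couples the spatial forward model with the real even SH basis evaluated
    at each slice's *reoriented* b-vector: slice i observes
    P_i (C @ Y(R_i g_i)) where C is the per-voxel coefficient vector.
    """
    slices = [np.asarray(s, dtype=float) for s in slices]
    if zs is None:
        raise ValueError("zs (geometric slice locations) required")
    nx, ny = slices[0].shape
    if shape is None:
        shape = (nx, ny, int(max(zs)))
    if slice_thickness is None:
        slice_thickness = voxel_size[2]
    if lambda_reg is None:
        lambda_reg = 0.01
    ncoef = n_sh_coeffs(l_max)
    gr = np.stack([reorient_bvec(g, T) for g, T in zip(gvecs, transforms)])
    # distinct directions up to antipodal symmetry
    uniq = []
    for g in gr:
        if not any(min(np.linalg.norm(g - u), np.linalg.norm(g + u)) < 1e-6
                   for u in uniq):
            uniq.append(g)
    if len(uniq) < ncoef:
        raise ValueError(
            f"shell has {len(uniq)} distinct reoriented directions but "
            f"l_max={l_max} needs {ncoef}; lower l_max")
    Y = real_sh_basis(l_max, gr)  # (n_slices, ncoef)
    w = np.asarray(weights, dtype=float)
    if np.any(w > 0):
        w = w / np.mean(w[w > 0])
    op = _SliceStackOperator(shape, voxel_size, zs, transforms,
                             slice_thickness, profile, n_taps)

    def forward(c):  # c: shape + (ncoef,)
        return [op.forward_one(c @ Y[i], i) for i in range(len(op))]

    def adjoint(res_list):
        out = np.zeros(shape + (ncoef,))
        for i, r in enumerate(res_list):
            out += op.adjoint_one(r, i)[..., None] * Y[i]
        return out

    b = adjoint([w[i] * s.ravel() for i, s in enumerate(slices)])

    def hess(c):
        pred = forward(c)
        out = adjoint([w[i] * p for i, p in enumerate(pred)])
        out += lambda_reg * _grad_sq_adjoint(c)
        return out

    x0 = np.zeros(shape + (ncoef,))
    c, _ = _cg(hess, b, x0, max_iter, tol)
    return SHCoefficientVolume(coeffs=c, b_value=b_value, l_max=l_max,
                               voxel_size=tuple(voxel_size))
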