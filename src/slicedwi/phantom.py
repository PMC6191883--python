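"""Digital diffusion phantom and forward acquisition model.

Generates all test data for the pipeline: a nested-ellipsoid "brain" with a
per-voxel diffusion tensor field, sinusoidal breathing motion traces, slowly
varying off-resonance field series, and a forward model producing
double-spin-echo slice stacks in which the second echo is acquired with the
phase-encoding polarity reversed (equal-opposite susceptibility distortion,
closely matched motion state).

The signal model is the monoexponential Stejskal-Tanner tensor model

    S = S0 * exp(-TE / T2) * exp(-b g^T D g),

with Gaussian noise added relative to the mean in-mask b=0 intensity.  The
generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .interp import slice_world_coords, trilinear_gather, world_coords, world_to_voxel
from .schedule import Schedule
from .transforms import RigidTransform

__all__ = [
    "Phantom",
    "PhantomSpec",
    "MotionTrace",
    "FieldSeries",
    "AcquiredDataset",
    "make_phantom",
    "breathing_trace",
    "dwi_signal",
    "apply_pe_displacement",
    "acquire",
    "gaussian_bump_field",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class Phantom:
    """Proton density, tensor field, T2 map and brain mask on one grid."""

    s0: np.ndarray          # (nx, ny, nz), arbitrary units
    tensors: np.ndarray     # (nx, ny, nz, 3, 3), mm^2/s
    t2: np.ndarray          # (nx, ny, nz), seconds
    mask: np.ndarray        # boolean
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        if not (self.s0.shape == self.t2.shape == self.mask.shape
                == self.tensors.shape[:3]):
            raise ValueError("phantom component shapes disagree")
        if np.any(self.s0 < 0):
            raise ValueError("proton density must be non-negative")

    @property
    def shape(self):
        return self.s0.shape


@dataclass(frozen=True)
class PhantomSpec:
    """Tissue parameters of the synthetic brain.

    ``anisotropy`` scales the deviatoric part of every tensor (0 gives
    per-voxel isotropic tensors); ``brain_fraction`` sets the through-slab
    extent of the brain relative to the field of view.
    """

    d_iso: float = 1.0e-3           # interior mean diffusivity, mm^2/s
    d_csf: float = 2.5e-3           # central "ventricle" diffusivity
    rim_eigvals: tuple[float, float, float] = (1.8e-3, 0.6e-3, 0.6e-3)  # FA ~ 0.6
    tract_eigvals: tuple[float, float, float] = (1.8e-3, 0.6e-3, 0.6e-3)
    anisotropy: float = 1.0
    brain_fraction: float = 0.92    # z-extent of brain / FOV
    inplane_fraction: float = 0.82  # x/y-extent of brain / FOV
    rim_start: float = 0.78         # normalized radius where the rim begins
    ventricle_radius: float = 0.28
    texture_amp: float = 0.25
    t2_interior: float = 0.15       # seconds
    t2_rim: float = 0.12
    t2_csf: float = 0.30


def _aniso_tensor(eigvals, direction, anisotropy) -> np.ndarray:
    """Tensor with given eigenvalues, principal axis ``direction`` (n, 3)."""
    lam1, lam2, lam3 = eigvals
    md = (lam1 + lam2 + lam3) / 3.0
    lam1 = md + anisotropy * (lam1 - md)
    lam23 = md + anisotropy * (lam2 - md)
    e1 = direction / np.linalg.norm(direction, axis=-1, keepdims=True)
    outer = e1[..., :, None] * e1[..., None, :]
    return lam23 * np.eye(3) + (lam1 - lam23) * outer


def make_phantom(shape, spec: PhantomSpec | None = None, seed: int = 0,
                 voxel_size=(2.2, 2.2, 2.2)) -> Phantom:
    """Nested-ellipsoid brain phantom.

    Isotropic interior, an anisotropic rim with radially oriented principal
    eigenvector, a central high-diffusivity "ventricle", and three
    anisotropic tracts (cylinders along x, y and z).  A smooth multiplicative
    texture on S0 provides registration contrast.
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or min(shape) < 4:
        raise ValueError(f"degenerate phantom shape {shape}")
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    X, Y, Z = world_coords(shape, voxel_size)
    fov = np.array(shape) * np.array(voxel_size)
    semi = np.array([
        spec.inplane_fraction * fov[0] / 2,
        spec.inplane_fraction * fov[1] / 2,
        spec.brain_fraction * fov[2] / 2,
    ])
    r = np.sqrt((X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2)
    mask = r < 1.0
    rim = (r >= spec.rim_start) & mask
    ventricle = r < spec.ventricle_radius

    # base isotropic tensors
    tensors = np.zeros(shape + (3, 3))
    tensors[...] = spec.d_iso * np.eye(3)
    tensors[ventricle] = spec.d_csf * np.eye(3)

    # rim: radially oriented anisotropy
    if np.any(rim):
        radial = np.stack([X[rim] / semi[0] ** 2, Y[rim] / semi[1] ** 2,
                           Z[rim] / semi[2] ** 2], axis=-1)
        radial /= np.maximum(np.linalg.norm(radial, axis=-1, keepdims=True), 1e-12)
        tensors[rim] = _aniso_tensor(spec.rim_eigvals, radial, spec.anisotropy)

    # three tracts: cylinders through the interior along x, y, z
    t2 = np.where(mask, spec.t2_interior, 1.0)
    t2[rim] = spec.t2_rim
    t2[ventricle] = spec.t2_csf
    tract_r = 0.18 * min(semi[0], semi[1])
    tract_specs = [
        (np.array([1.0, 0, 0]), (Y - 0.45 * semi[1]) ** 2 + (Z - 0.2 * semi[2]) ** 2),
        (np.array([0, 1.0, 0]), (X + 0.45 * semi[0]) ** 2 + (Z + 0.2 * semi[2]) ** 2),
        (np.array([0, 0, 1.0]), (X - 0.35 * semi[0]) ** 2 + (Y + 0.35 * semi[1]) ** 2),
    ]
    for axis_dir, dist2 in tract_specs:
        sel = mask & ~rim & ~ventricle & (dist2 < tract_r**2)
        if np.any(sel):
            tensors[sel] = _aniso_tensor(
                spec.tract_eigvals, np.broadcast_to(axis_dir, (int(sel.sum()), 3)),
                spec.anisotropy)

    texture = gaussian_filter(rng.standard_normal(shape), sigma=1.5)
    texture /= max(texture.std(), 1e-12)
    s0 = np.where(mask, 1.0, 0.0)
    s0[rim] = 0.85
    s0[ventricle] = 1.3
    s0 *= np.clip(1.0 + spec.texture_amp * texture, 0.3, 2.0)
    s0[~mask] = 0.0
    return Phantom(s0=s0, tensors=tensors, t2=t2, mask=mask,
                   voxel_size=tuple(float(v) for v in voxel_size))


@dataclass(frozen=True)
class MotionTrace:
    """Object pose at every slice excitation (world-coordinate transforms)."""

    times: np.ndarray
    transforms: tuple[RigidTransform, ...]

    def __post_init__(self):
        if len(self.times) != len(self.transforms):
            raise ValueError("times and transforms length mismatch")

    def __len__(self):
        return len(self.transforms)


def breathing_trace(tr: float, n_slices: int, n_volumes: int,
                    amplitude_mm: float = 4.0, period_s: float = 5.0,
                    axis: str = "y") -> MotionTrace:
    """Sinusoidal breathing displacement sampled at every slice time.

    Pure translation d(t) = A sin(2 pi t / T) along ``axis``, sampled at
    t = k * TR / Ns for k = 0 .. Ns*Nv - 1.
    """
    if amplitude_mm < 0 or period_s <= 0:
        raise ValueError("amplitude must be >= 0 and period > 0")
    ax = _AXES[axis]
    times = np.arange(n_slices * n_volumes) * (tr / n_slices)
    disp = amplitude_mm * np.sin(2 * np.pi * times / period_s)
    transforms = []
    for d in disp:
        t = np.zeros(3)
        t[ax] = d
        transforms.append(RigidTransform.from_translation(t))
    return MotionTrace(times=times, transforms=tuple(transforms))


@dataclass(frozen=True)
class FieldSeries:
    """Off-resonance maps (Hz) at given timestamps."""

    timestamps: np.ndarray
    fields: tuple[np.ndarray, ...]

    def __post_init__(self):
        if len(self.timestamps) != len(self.fields):
            raise ValueError("timestamps and fields length mismatch")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")

    def at(self, time: float) -> np.ndarray:
        """Field map whose timestamp is nearest to ``time`` (ties: earlier)."""
        dt = np.abs(np.asarray(self.timestamps) - time)
        return self.fields[int(np.argmin(dt))]


def gaussian_bump_field(shape, peak_hz: float, centre_frac=(0.5, 0.35, 0.5),
                        width_frac: float = 0.18) -> np.ndarray:
    """Smooth localized off-resonance bump, vanishing towards the edges."""
    idx = np.indices(shape).astype(float)
    g = np.ones(shape)
    for ax in range(3):
        c = centre_frac[ax] * (shape[ax] - 1)
        w = width_frac * shape[ax]
        g *= np.exp(-((idx[ax] - c) ** 2) / (2 * w**2))
    return peak_hz * g


def dwi_signal(phantom: Phantom, b: float, g, te: float) -> np.ndarray:
    """Noise-free diffusion-weighted volume for one encoding.

    S = S0 exp(-TE/T2) exp(-b g^T D g); ``g`` must be unit length for b > 0.
    """
    g = np.asarray(g, dtype=float)
    if b > 0 and abs(np.linalg.norm(g) - 1.0) > 1e-6:
        raise ValueError(f"b-vector must be unit length for b > 0, |g|={np.linalg.norm(g):.4f}")
    atten = np.ones(phantom.shape)
    if b > 0:
        quad = np.einsum("...ij,i,j->...", phantom.tensors, g, g)
        atten = np.exp(-b * quad)
    return phantom.s0 * np.exp(-te / phantom.t2) * atten


def _pe_warp(y: np.ndarray, shift: np.ndarray) -> np.ndarray:
    phi = y + shift
    if np.any(np.diff(phi) <= 0):
        raise ValueError("PE displacement field folds the image (non-monotone warp)")
    return phi


def apply_pe_displacement(slice_img: np.ndarray, field_hz: np.ndarray,
                          pe_sign: int, pixel_bandwidth_pe: float) -> np.ndarray:
    """Susceptibility distortion of one slice along the PE axis (axis 1).

    Signal at true position y appears at y + s(y) with
    s = pe_sign * field / bandwidth (pixels); intensity follows the Jacobian
    of the warp, so stretched regions dim and compressed regions pile up.
    Total intensity is conserved for fields vanishing at the edges.
    """
    from scipy.ndimage import map_coordinates

    img = np.asarray(slice_img, dtype=float)
    shift = pe_sign * np.asarray(field_hz, dtype=float) / pixel_bandwidth_pe
    nx, ny = img.shape
    if np.max(np.abs(shift)) > ny / 2:
        raise ValueError("PE shift exceeds half the field of view")
    y = np.arange(ny, dtype=float)
    y_src = np.empty_like(img)
    jac = np.empty_like(img)
    for col in range(nx):
        phi = _pe_warp(y, shift[col])
        dphi = np.gradient(phi)
        # inverse map: y_src(y_out) with phi(y_src) = y_out
        ys = np.interp(y, phi, y, left=y[0] - (phi[0] - y[0]),
                       right=y[-1] - (phi[-1] - y[-1]))
        y_src[col] = ys
        jac[col] = np.interp(ys, y, dphi)
    rows = np.broadcast_to(np.arange(nx, dtype=float)[:, None], img.shape)
    warped = map_coordinates(img, [rows, y_src], order=3, mode="constant")
    return warped / jac


@dataclass(frozen=True)
class AcquiredDataset:
    """Per-slice images for one or two echoes plus simulation ground truth."""

    schedule: Schedule
    slices: dict          # echo index -> array (Nt, nx, ny)
    te: tuple[float, ...]
    truth_motion: MotionTrace | None
    truth_fields: FieldSeries | None
    noise_sigma: float
    seed: int
    grid_shape: tuple[int, int, int]

    @property
    def double_echo(self) -> bool:
        return 2 in self.slices

    def echo(self, e: int) -> np.ndarray:
        return self.slices[e]

    def pe_sign(self, e: int) -> int:
        """Echo 1 is acquired blip-up (+1), echo 2 blip-down (-1)."""
        return 1 if e == 1 else -1


def _is_translation_only(motion: MotionTrace | None) -> bool:
    if motion is None:
        return True
    return all(np.allclose(t.rotation, np.eye(3), atol=1e-12)
               for t in motion.transforms)


def acquire(phantom: Phantom, schedule: Schedule,
            motion: MotionTrace | None = None,
            field_series: FieldSeries | None = None,
            noise_sigma: float = 0.0, seed: int = 0,
            double_echo: bool = False,
            te: tuple[float, float] = (0.107, 0.208)) -> AcquiredDataset:
    """Forward-simulate a slice-level acquisition.

    For every tag the phantom is moved by that excitation's rigid transform,
    the diffusion-weighted signal for its encoding evaluated at TE1, the
    geometric slice extracted, and the PE displacement of the current field
    applied with positive polarity.  With ``double_echo`` the same slice is
    produced again at TE2 with reversed polarity.  Gaussian noise with
    standard deviation ``noise_sigma`` relative to the mean in-mask b=0
    intensity is added last.
    """
    geo = schedule.geometry
    nx, ny, nz = phantom.shape
    if nz != geo.n_slices:
        raise ValueError(
            f"phantom has {nz} slices but geometry expects {geo.n_slices}")
    if motion is not None and len(motion) != schedule.n_tags:
        raise ValueError("motion trace length does not match schedule")
    rng = np.random.default_rng(seed)
    echoes = (1, 2) if double_echo else (1,)
    scheme = schedule.scheme
    translation_only = _is_translation_only(motion)

    # world pixel coordinates per geometric slice
    slice_coords = {z: slice_world_coords(phantom.shape, phantom.voxel_size, z)
                    for z in range(1, nz + 1)}
    times = schedule.times()

    signal_cache: dict = {}

    def signal_volume(d: int, e: int) -> np.ndarray:
        key = (d, e)
        if key not in signal_cache:
            signal_cache[key] = dwi_signal(
                phantom, scheme.bvals[d - 1], scheme.bvecs[d - 1], te[e - 1])
        return signal_cache[key]

    s0e = {e: phantom.s0 * np.exp(-te[e - 1] / phantom.t2) for e in echoes}
    tensor_comps = None

    out = {e: np.zeros((schedule.n_tags, nx, ny)) for e in echoes}
    for tag in schedule.tags:
        X = slice_coords[tag.z]
        if motion is not None:
            M_inv = motion.transforms[tag.t].inverse()
            Xp = M_inv.apply(X)
        else:
            Xp = X
        vox = world_to_voxel(Xp, phantom.shape, phantom.voxel_size)
        for e in echoes:
            if motion is None:
                img = signal_volume(tag.d, e)[:, :, tag.z - 1]
            elif translation_only or scheme.bvals[tag.d - 1] == 0:
                img = trilinear_gather(signal_volume(tag.d, e), vox).reshape(nx, ny)
            else:
                # rotation reorients the tensor field: sample raw tensors and
                # evaluate the quadratic form with the back-rotated gradient
                if tensor_comps is None:
                    tensor_comps = [
                        phantom.tensors[..., i, j]
                        for i, j in ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))
                    ]
                base = trilinear_gather(s0e[e], vox)
                comps = [trilinear_gather(c, vox) for c in tensor_comps]
                gt = motion.transforms[tag.t].rotation.T @ scheme.bvecs[tag.d - 1]
                quad = (comps[0] * gt[0] ** 2 + comps[1] * gt[1] ** 2
                        + comps[2] * gt[2] ** 2
                        + 2 * (comps[3] * gt[0] * gt[1]
                               + comps[4] * gt[0] * gt[2]
                               + comps[5] * gt[1] * gt[2]))
                img = (base * np.exp(-scheme.bvals[tag.d - 1] * quad)).reshape(nx, ny)
            if field_series is not None:
                fmap = field_series.at(times[tag.t])
                img = apply_pe_displacement(
                    img, fmap[:, :, tag.z - 1],
                    pe_sign=1 if e == 1 else -1,
                    pixel_bandwidth_pe=geo.pixel_bandwidth_pe)
            out[e][tag.t] = img

    if noise_sigma > 0:
        ref = float(np.mean(phantom.s0[phantom.mask]
                            * np.exp(-te[0] / phantom.t2[phantom.mask])))
        for e in echoes:
            out[e] += rng.normal(0.0, noise_sigma * ref, size=out[e].shape)

    return AcquiredDataset(schedule=schedule, slices=out, te=tuple(te[:len(echoes)]),
                           truth_motion=motion, truth_fields=field_series,
                           noise_sigma=noise_sigma, seed=seed,
                           grid_shape=(nx, ny, nz))
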