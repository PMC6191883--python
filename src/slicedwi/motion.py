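"""Slice-wise motion estimation from densely sampled low-b slices.

The pipeline: (1) brain masking of a b=0 volume by intensity thresholding,
largest-connected-component selection and median filtering; (2) per-slice
weights from the in-mask voxel fraction, with slices below 1% flagged as
outliers; (3) slice-to-volume registration (SVR) of the low-b slices,
alternating rigid registration against an evolving 3-D target with
scattered-slice reconstruction of that target; (4) assignment of poses to
all high-b slices by SE(3) geodesic interpolation between the two
temporally closest non-outlier low-b slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from skimage.filters import threshold_otsu

from .interp import slice_world_coords, trilinear_gather, world_to_voxel
from .phantom import AcquiredDataset, MotionTrace
from .schedule import Schedule, SliceTag
from .transforms import RigidTransform, interp_rigid  # noqa: F401 (re-export)
from . import recon

__all__ = [
    "SliceWeight",
    "brain_mask",
    "slice_weights",
    "register_slice_to_volume",
    "svr_low_b",
    "interp_rigid",
    "assign_transforms",
    "mean_displacement_error",
]

log = logging.getLogger(__name__)

OUTLIER_FRACTION = 0.01  # slices with < 1% in-mask voxels are outliers


@dataclass(frozen=True)
class SliceWeight:
    """Registration reliability of one slice: in-mask fraction in [0, 1]."""

    tag: SliceTag | None
    in_mask_fraction: float
    weight: float
    outlier: bool


def brain_mask(volume: np.ndarray) -> np.ndarray:
    """Binary brain mask: Otsu threshold, largest 26-connected component,
    3-D median filter of radius 1."""
    volume = np.asarray(volume, dtype=float)
    if np.ptp(volume) == 0:
        raise ValueError("cannot mask a constant volume")
    thr = threshold_otsu(volume)
    raw = volume > thr
    labels, n = ndimage.label(raw, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        raise ValueError("no foreground voxels above threshold")
    sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
    largest = (labels == (1 + int(np.argmax(sizes))))
    # constant padding: reflect would double boundary layers and inflate the
    # mask into empty edge slices
    return ndimage.median_filter(largest.astype(np.uint8), size=3,
                                 mode="constant", cval=0).astype(bool)


def slice_weights(mask: np.ndarray, schedule: Schedule) -> list[SliceWeight]:
    """Weight every tag by the in-mask voxel fraction of its slice location."""
    nz = mask.shape[2]
    if nz != schedule.geometry.n_slices:
        raise ValueError("mask slice count does not match schedule geometry")
    per_pixel = mask.shape[0] * mask.shape[1]
    frac = {z: float(mask[:, :, z - 1].sum()) / per_pixel
            for z in range(1, nz + 1)}
    out = []
    for tag in schedule.tags:
        f = frac[tag.z]
        outlier = f < OUTLIER_FRACTION
        out.append(SliceWeight(tag=tag, in_mask_fraction=f,
                               weight=0.0 if outlier else f, outlier=outlier))
    return out


def _params_matrix(params) -> np.ndarray:
    """Fast (unvalidated) 4x4 from (tx, ty, tz, rx, ry, rz[deg]), matching
    RigidTransform.from_params with centre at the world origin."""
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(np.radians(rx)), np.sin(np.radians(rx))
    cy, sy = np.cos(np.radians(ry)), np.sin(np.radians(ry))
    cz, sz = np.cos(np.radians(rz)), np.sin(np.radians(rz))
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    m = np.eye(4)
    m[:3, :3] = Rz @ Ry @ Rx  # extrinsic xyz, matching scipy's "xyz" Euler
    m[:3, 3] = (tx, ty, tz)
    return m


def _mse_cost(points_w: np.ndarray, values: np.ndarray, target: np.ndarray,
              shape, voxel_size):
    offset = np.array([(shape[ax] - 1) / 2.0 for ax in range(3)])[:, None]
    inv_h = (1.0 / np.asarray(voxel_size, dtype=float))[:, None]
    hi = np.array([shape[ax] - 1 for ax in range(3)], dtype=float)[:, None]

    def cost(params):
        m = _params_matrix(params)
        pts = m[:3, :3] @ points_w + m[:3, 3][:, None]
        vox = pts * inv_h + offset
        # snap float-rounding spill at the volume faces: scipy's constant
        # mode zeroes a sample that is even 1e-16 outside the grid
        np.copyto(vox, 0.0, where=(vox > -1e-6) & (vox < 0))
        np.copyto(vox, hi, where=(vox > hi) & (vox < hi + 1e-6))
        pred = ndimage.map_coordinates(target, vox, order=1, mode="constant")
        return float(np.mean((pred - values) ** 2))
    return cost


_LEVELS_FULL = ((2, 1.0, 2), (1, 0.0, 3))    # (stride, smooth sigma, maxiter)
_LEVELS_REFINE = ((1, 0.0, 2),)              # warm-started refinement
_LEVELS_PRECISE = ((2, 1.0, 3), (1, 0.0, 6))  # standalone, accuracy first


def _register_points(points_w, values, target, voxel_size, init_params,
                     levels=_LEVELS_FULL, xtol=2e-2, ftol=1e-3):
    """Multi-resolution rigid registration by Powell's method.

    The result is only accepted if it actually lowers the full-resolution
    cost relative to the initial parameters; on flat or featureless cost
    surfaces the optimizer can wander, and the init is then kept.
    """
    init_params = np.asarray(init_params, dtype=float)
    params = init_params
    shape = target.shape
    cost_full = _mse_cost(points_w, values, target, shape, voxel_size)
    for stride, sigma, maxiter in levels:
        tgt = ndimage.gaussian_filter(target, sigma) if sigma > 0 else target
        pts = points_w[:, ::stride]
        vals = values[::stride]
        cost = _mse_cost(pts, vals, tgt, shape, voxel_size)
        res = minimize(cost, params, method="Powell",
                       options={"xtol": xtol, "ftol": ftol,
                                "maxiter": maxiter, "maxfev": 3000})
        params = res.x
    if cost_full(params) >= cost_full(init_params):
        return init_params
    return params


def register_slice_to_volume(slice_img: np.ndarray, tag: SliceTag,
                             target_volume: np.ndarray,
                             init_transform: RigidTransform,
                             voxel_size=(2.2, 2.2, 2.2),
                             target_mask: np.ndarray | None = None,
                             levels=_LEVELS_PRECISE,
                             ) -> tuple[RigidTransform, bool]:
    """Rigidly register one 2-D slice into the 3-D target.

    Minimizes the mean squared intensity difference between the slice and
    the target resampled at the (rigidly moved) slice plane, with a
    derivative-free optimizer and a 2-level multi-resolution schedule.  The
    returned transform maps slice/native coordinates into anatomical (target)
    space.  Registration is declared unsuccessful — and the initial transform
    returned — when less than 1% of the slice overlaps the target mask under
    the initial transform.
    """
    target_volume = np.asarray(target_volume, dtype=float)
    if np.ptp(target_volume) == 0:
        raise ValueError("registration target is empty/constant")
    if target_mask is None:
        target_mask = target_volume > 0.5 * threshold_otsu(target_volume)
    X = slice_world_coords(target_volume.shape, voxel_size, tag.z)
    maskf = target_mask.astype(float)

    def overlap_at(transform: RigidTransform) -> float:
        vox = world_to_voxel(transform.apply(X), target_volume.shape,
                             voxel_size)
        return float(np.mean(trilinear_gather(maskf, vox) > 0.5))

    overlap0 = overlap_at(init_transform)
    if overlap0 < OUTLIER_FRACTION:
        return init_transform, False
    values = np.asarray(slice_img, dtype=float).ravel()
    params = _register_points(X, values, target_volume, voxel_size,
                              init_transform.to_params(), levels=levels)
    result = RigidTransform.from_params(params)
    # a "better" fit that slides the slice off the brain is an escape into
    # empty background, not a registration; revert to the initial pose
    if overlap_at(result) < 0.5 * overlap0:
        return init_transform, False
    return result, True


def _register_volume(volume: np.ndarray, target: np.ndarray, voxel_size,
                     init: RigidTransform, support: np.ndarray) -> RigidTransform:
    """Volume-to-volume rigid registration over the support voxels."""
    idx = np.argwhere(support)[::2].T  # stride-2 subsample for speed
    pts = np.stack([
        (idx[ax] - (volume.shape[ax] - 1) / 2.0) * voxel_size[ax]
        for ax in range(3)
    ])
    vals = volume[tuple(idx)]
    params = _register_points(pts, vals, target, voxel_size, init.to_params())
    return RigidTransform.from_params(params)


def _register_group(dataset: AcquiredDataset, tags, target, voxel_size,
                    init: RigidTransform, maxiter: int = 4,
                    stride: int = 2) -> RigidTransform:
    """Jointly register a temporally compact group of slices as one rigid body."""
    pts = np.concatenate(
        [slice_world_coords(target.shape, voxel_size, tag.z)
         for tag in tags], axis=1)
    vals = np.concatenate(
        [dataset.echo(1)[tag.t].ravel() for tag in tags])
    params = _register_points(
        pts[:, ::stride], vals[::stride], target, voxel_size,
        init.to_params(), levels=((1, 0.5, maxiter),))
    return RigidTransform.from_params(params)


def _assemble_superblock_b0(dataset: AcquiredDataset, echo: int = 1):
    """Per-superblock b=0 volumes: one slice per location from each block."""
    sched = dataset.schedule
    nx, ny, nz = dataset.grid_shape
    data = dataset.echo(echo)
    vols: dict[int, np.ndarray] = {}
    members: dict[int, list[SliceTag]] = {}
    for tag in sched.low_b_tags():
        vols.setdefault(tag.l, np.zeros((nx, ny, nz)))
        vols[tag.l][:, :, tag.z - 1] = data[tag.t]
        members.setdefault(tag.l, []).append(tag)
    return vols, members


def temporal_smooth_transforms(times: dict[int, float],
                               transforms: dict[int, "RigidTransform"],
                               outliers: set[int],
                               half_width_s: float = 0.3,
                               sigma_s: float = 0.15) -> dict[int, "RigidTransform"]:
    """Regularize pose estimates over acquisition time.

    Physiological motion is smooth on the slice-time scale, and the
    interleave places temporally adjacent low-b slices at spatially distant
    locations, so averaging each pose with its temporal neighbours (Gaussian
    weights in se(3) log space, window +- ``half_width_s`` seconds) both
    damps independent registration noise and breaks the per-location shear
    mode that per-slice registration against a reconstructed target cannot
    observe.  Outlier slices contribute nothing and keep their own pose.
    """
    from .transforms import se3_exp, se3_log

    ts = sorted(t for t in transforms if t not in outliers)
    if not ts:
        return dict(transforms)
    tarr = np.array([times[t] for t in ts])
    logs = {t: se3_log(transforms[t]) for t in ts}
    out = dict(transforms)
    for t in ts:
        dt = np.abs(tarr - times[t])
        sel = dt <= half_width_s
        w = np.exp(-0.5 * (dt[sel] / sigma_s) ** 2)
        if w.sum() <= 0:
            continue
        acc = np.zeros((4, 4))
        for wi, ti in zip(w, np.array(ts)[sel]):
            acc += wi * logs[int(ti)]
        out[t] = se3_exp(acc / w.sum())
    return out


def svr_low_b(dataset: AcquiredDataset, n_iterations: int = 3,
              lambda_reg: float | None = None,
              temporal_half_width_s: float = 0.3):
    """Slice-to-volume registration of the low-b stream.

    Coarse-to-fine in *temporal extent*: the low-b slices are first grouped
    per volume and each group registered as a rigid body against the
    voxelwise median of the per-superblock assembled b=0 volumes; groups are
    then split and re-registered until every individual slice is refined on
    its own (``n_iterations`` per-slice passes).  Between stages the target
    is rebuilt by scattered-slice least-squares reconstruction from the
    current poses.  Returns ``(target_volume, {t: RigidTransform}, weights)``.
    """
    sched = dataset.schedule
    voxel = sched.geometry.voxel_size
    vols, members = _assemble_superblock_b0(dataset)
    low_tags = sorted((t for tags in members.values() for t in tags),
                      key=lambda tag: tag.t)
    zs = {tag.z for tag in low_tags}
    if len(vols) < 1 or len(zs) < sched.geometry.n_slices:
        raise ValueError("insufficient low-b data for slice-to-volume registration")
    per_z = min(sum(1 for t in low_tags if t.z == z) for z in zs)
    if per_z < 2:
        raise ValueError("need at least 2 low-b slices per location")

    # the MEAN over assembled volumes: periodic motion averages to zero
    # displacement at every location, so the initial target is blurred but
    # unbiased; a median would freeze the per-location displacement of the
    # middle motion phase into the target
    target = np.mean(np.stack(list(vols.values())), axis=0)
    mask = brain_mask(target)
    weights = slice_weights(mask, sched)
    wmap = {w.tag.t: w for w in weights}
    transforms: dict[int, RigidTransform] = {
        tag.t: RigidTransform.identity() for tag in low_tags}

    def rebuild_target(final: bool = False):
        slc, trf, wts = [], [], []
        for tag in low_tags:
            slc.append(dataset.echo(1)[tag.t])
            trf.append(transforms[tag.t])
            wts.append(wmap[tag.t].weight)
        vol, info = recon.reconstruct_volume(
            slc, trf, wts, voxel_size=voxel,
            zs=[tag.z for tag in low_tags],
            shape=(dataset.grid_shape[0], dataset.grid_shape[1],
                   sched.geometry.n_slices),
            slice_thickness=sched.geometry.slice_thickness,
            lambda_reg=lambda_reg,
            profile="gaussian" if final else "delta",
            max_iter=15 if final else 6, return_info=True)
        # regularization fills voxels no weighted slice observes; those are
        # invented content and must not enter the mask
        m = brain_mask(vol) & info["covered"]
        return vol, m

    # temporal group sizes: one volume's worth, a quarter of that, then singles
    g1 = max(len(low_tags) // sched.n_volumes, 1)
    stages = [g1]
    if g1 > 3:
        stages.append(max(g1 // 4, 1))
    stages.extend([1] * n_iterations)

    for si, g in enumerate(stages):
        last = si == len(stages) - 1
        if g > 1:
            groups = [low_tags[i:i + g] for i in range(0, len(low_tags), g)]
            for grp in groups:
                init = transforms[grp[len(grp) // 2].t]
                informative = [tag for tag in grp
                               if not wmap[tag.t].outlier]
                T = (_register_group(dataset, informative, target, voxel, init)
                     if informative else init)
                for tag in grp:
                    transforms[tag.t] = T
        else:
            n_fail = 0
            levels = _LEVELS_FULL if stages[si - 1] != 1 else _LEVELS_REFINE
            for tag in low_tags:
                T, ok = register_slice_to_volume(
                    dataset.echo(1)[tag.t], tag, target, transforms[tag.t],
                    voxel_size=voxel, target_mask=mask, levels=levels)
                transforms[tag.t] = T
                n_fail += not ok
            log.info("svr per-slice stage: %d/%d registrations skipped",
                     n_fail, len(low_tags))
            if temporal_half_width_s > 0:
                times = {tag.t: tag.t * sched.geometry.slice_time
                         for tag in low_tags}
                outliers = {tag.t for tag in low_tags
                            if wmap[tag.t].outlier}
                transforms = temporal_smooth_transforms(
                    times, transforms, outliers,
                    half_width_s=temporal_half_width_s)
        target, mask = rebuild_target(final=last)
        weights = slice_weights(mask, sched)
        wmap = {w.tag.t: w for w in weights}
    return target, transforms, weights


def assign_transforms(schedule: Schedule,
                      low_b_transforms: dict[int, RigidTransform],
                      weights: list[SliceWeight]) -> list[RigidTransform]:
    """Pose for every slice by interpolating between low-b neighbours.

    Non-outlier low-b slices keep their registered transform.  Every other
    slice at time t between the two temporally closest non-outlier low-b
    slices (t0 < t < t1) gets interp_rigid(R0, R1, (t-t0)/(t1-t0)); outlier
    low-b slices are skipped when selecting neighbours.  Slices before the
    first / after the last usable low-b slice are clamped to it.
    """
    wmap = {w.tag.t: w for w in weights}
    usable = sorted(
        t for t in low_b_transforms
        if t in wmap and not wmap[t].outlier
    )
    if not usable:
        raise ValueError("all low-b slices are outliers; cannot interpolate")
    times = np.array(usable, dtype=float)  # slice index is proportional to time
    out: list[RigidTransform] = []
    for tag in schedule.tags:
        t = tag.t
        if t in low_b_transforms and t in wmap and not wmap[t].outlier:
            out.append(low_b_transforms[t])
            continue
        i = int(np.searchsorted(times, t))
        if i == 0:
            out.append(low_b_transforms[usable[0]])
        elif i == len(times):
            out.append(low_b_transforms[usable[-1]])
        else:
            t0, t1 = times[i - 1], times[i]
            tau = (t - t0) / (t1 - t0)
            out.append(interp_rigid(low_b_transforms[usable[i - 1]],
                                    low_b_transforms[usable[i]], tau))
    return out


def mean_displacement_error(estimated: list[RigidTransform],
                            truth: MotionTrace,
                            weights: list[SliceWeight],
                            axis: str = "y") -> float:
    """Mean |estimated - true| translation (mm) along one axis.

    The estimated transforms map slices into anatomical space, i.e. they
    undo the simulated object motion, so the truth is the *negated* motion
    translation.  Slices whose z-location holds < 1% in-mask voxels are
    excluded, as are any remaining outlier-flagged slices.
    """
    if len(estimated) != len(truth) or len(estimated) != len(weights):
        raise ValueError("length mismatch between estimates, truth and weights")
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    errs = []
    for est, mot, w in zip(estimated, truth.transforms, weights):
        if w.outlier:
            continue
        errs.append(abs(est.translation[ax] - (-mot.translation[ax])))
    if not errs:
        raise ValueError("all slices excluded")
    return float(np.mean(errs))
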