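"""Masking, slice weighting, registration and transform assignment."""

import numpy as np
import pytest

from slicedwi import motion as mo
from slicedwi import phantom as ph
from slicedwi import schedule as sch
from slicedwi.motion import (assign_transforms, brain_mask,
                             mean_displacement_error,
                             register_slice_to_volume, slice_weights,
                             svr_low_b)
from slicedwi.transforms import RigidTransform


class TestBrainMask:
    def test_phantom_mask_recovered(self, small_phantom, small_b0):
        mask = brain_mask(small_b0)
        inter = np.logical_and(mask, small_phantom.mask).sum()
        dice = 2 * inter / (mask.sum() + small_phantom.mask.sum())
        assert dice > 0.95

    def test_largest_component_kept(self):
        vol = np.zeros((24, 24, 12))
        vol[2:12, 2:12, 2:10] = 1.0     # large blob
        vol[16:20, 16:20, 2:6] = 1.0    # small blob
        mask = brain_mask(vol)
        assert mask[4:10, 4:10, 4:8].all()
        assert not mask[16:20, 16:20, 2:6].any()

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            brain_mask(np.zeros((8, 8, 8)))


class TestSliceWeights:
    def _schedule(self, ns=12):
        geo = sch.AcquisitionGeometry(n_slices=ns, tr=3.0)
        return sch.build_schedule(sch.make_superblock_scheme(2, 2), geo, L=2)

    def test_fraction_arithmetic(self):
        s = self._schedule()
        mask = np.zeros((50, 50, 12), dtype=bool)
        mask[:25, :20, 0] = True  # 500 of 2500 voxels in slice z=1
        ws = slice_weights(mask, s)
        w1 = [w for w in ws if w.tag.z == 1][0]
        assert w1.in_mask_fraction == pytest.approx(0.2)
        assert w1.weight == pytest.approx(0.2)
        assert not w1.outlier

    def test_sub_percent_slice_is_outlier(self):
        s = self._schedule()
        mask = np.zeros((50, 50, 12), dtype=bool)
        mask[:4, :5, 1] = True  # 20 voxels = 0.8%
        ws = slice_weights(mask, s)
        w2 = [w for w in ws if w.tag.z == 2][0]
        assert w2.in_mask_fraction == pytest.approx(0.008)
        assert w2.weight == 0.0 and w2.outlier

    def test_empty_slice_is_outlier(self):
        s = self._schedule()
        mask = np.zeros((50, 50, 12), dtype=bool)
        mask[:, :, 3] = True
        ws = slice_weights(mask, s)
        w1 = [w for w in ws if w.tag.z == 1][0]
        assert w1.weight == 0.0 and w1.outlier


class TestRegisterSliceToVolume:
    def test_self_registration_is_identity(self, small_phantom, small_b0):
        tag = sch.SliceTag(t=6, d=1, v=1, s=7, z=6, l=1)
        T, ok = register_slice_to_volume(
            small_b0[:, :, 5], tag, small_b0, RigidTransform.identity(),
            voxel_size=small_phantom.voxel_size)
        assert ok
        p = T.to_params()
        assert np.abs(p[:3]).max() < 0.05      # mm
        assert np.abs(p[3:]).max() < 0.05      # degrees

    def test_object_shift_recovered_with_negated_sign(self, small_phantom,
                                                      small_b0):
        geo = sch.AcquisitionGeometry(n_slices=12, tr=3.0)
        s = sch.build_schedule(sch.make_superblock_scheme(2, 2), geo, L=2)
        move = RigidTransform.from_translation([0, 3.0, 0])
        trace = ph.MotionTrace(times=np.arange(s.n_tags) * geo.slice_time,
                               transforms=(move,) * s.n_tags)
        ds = ph.acquire(small_phantom, s, motion=trace)
        tag = [t for t in s.tags if t.z == 6][0]
        T, ok = register_slice_to_volume(
            ds.echo(1)[tag.t], tag, small_b0, RigidTransform.identity(),
            voxel_size=small_phantom.voxel_size)
        assert ok
        assert T.translation[1] == pytest.approx(-3.0, abs=0.2)

    def test_featureless_slice_returns_init(self, small_phantom, small_b0):
        # top slice: phantom mask is empty there
        tag = sch.SliceTag(t=0, d=1, v=1, s=1, z=12, l=1)
        init = RigidTransform.from_translation([1.0, 0, 0])
        T, ok = register_slice_to_volume(
            np.zeros_like(small_b0[:, :, 11]), tag, small_b0, init,
            voxel_size=small_phantom.voxel_size,
            target_mask=small_phantom.mask)
        assert not ok
        np.testing.assert_array_equal(T.matrix, init.matrix)

    def test_empty_target_rejected(self, small_phantom):
        tag = sch.SliceTag(t=0, d=1, v=1, s=1, z=6, l=1)
        with pytest.raises(ValueError):
            register_slice_to_volume(np.zeros((24, 24)), tag,
                                     np.zeros((24, 24, 12)),
                                     RigidTransform.identity())


def _weights_for(schedule, outlier_ts=()):
    ws = []
    for tag in schedule.tags:
        out = tag.t in outlier_ts
        ws.append(mo.SliceWeight(tag=tag, in_mask_fraction=0.0 if out else 0.5,
                                 weight=0.0 if out else 0.5, outlier=out))
    return ws


class TestAssignTransforms:
    def _schedule(self):
        geo = sch.AcquisitionGeometry(n_slices=4, tr=4.0)
        return sch.build_schedule(sch.make_superblock_scheme(2, 2), geo, L=2)

    def test_midpoint_interpolation(self):
        s = self._schedule()
        low_ts = [tag.t for tag in s.low_b_tags()]
        trs = {low_ts[0]: RigidTransform.from_translation([0, 0, 0]),
               low_ts[1]: RigidTransform.from_translation([0, 2.0, 0])}
        # keep only two low-b anchors
        ws = _weights_for(s, outlier_ts=set(low_ts[2:]))
        trs.update({t: RigidTransform.identity() for t in low_ts[2:]})
        series = assign_transforms(s, trs, ws)
        mid_t = (low_ts[0] + low_ts[1]) // 2
        if (low_ts[0] + low_ts[1]) % 2 == 0:
            expected = 2.0 * (mid_t - low_ts[0]) / (low_ts[1] - low_ts[0])
            assert series[mid_t].translation[1] == pytest.approx(expected)

    def test_outlier_neighbour_skipped(self):
        s = self._schedule()
        low_ts = [tag.t for tag in s.low_b_tags()]
        trs = {t: RigidTransform.from_translation([0, float(i), 0])
               for i, t in enumerate(low_ts)}
        # corrupt the second anchor and flag it
        trs[low_ts[1]] = RigidTransform.from_translation([0, 99.0, 0])
        ws = _weights_for(s, outlier_ts={low_ts[1]})
        series = assign_transforms(s, trs, ws)
        # a slice between anchors 0 and 2 interpolates across the gap
        t_query = low_ts[1]
        tau = (t_query - low_ts[0]) / (low_ts[2] - low_ts[0])
        expected = 0.0 * (1 - tau) + 2.0 * tau
        assert series[t_query].translation[1] == pytest.approx(expected)
        assert abs(series[t_query].translation[1]) < 50

    def test_clamped_before_first_anchor(self):
        s = self._schedule()
        low_ts = [tag.t for tag in s.low_b_tags()]
        trs = {t: RigidTransform.from_translation([0, 1.0 + i, 0])
               for i, t in enumerate(low_ts)}
        ws = _weights_for(s)
        series = assign_transforms(s, trs, ws)
        for t in range(low_ts[0]):
            assert series[t].translation[1] == pytest.approx(1.0)

    def test_all_outliers_rejected(self):
        s = self._schedule()
        low_ts = [tag.t for tag in s.low_b_tags()]
        trs = {t: RigidTransform.identity() for t in low_ts}
        ws = _weights_for(s, outlier_ts=set(low_ts))
        with pytest.raises(ValueError):
            assign_transforms(s, trs, ws)


class TestMeanDisplacementError:
    def _setup(self, offsets):
        geo = sch.AcquisitionGeometry(n_slices=4, tr=4.0)
        s = sch.build_schedule(sch.make_superblock_scheme(1, 2), geo, L=2)
        truth = ph.MotionTrace(
            times=np.arange(s.n_tags) * geo.slice_time,
            transforms=tuple(RigidTransform.from_translation([0, 0, 0])
                             for _ in range(s.n_tags)))
        est = [RigidTransform.from_translation([0, o, 0]) for o in offsets]
        return s, est, truth

    def test_exact_estimates_give_zero(self):
        s, est, truth = self._setup([0.0] * 8)
        assert mean_displacement_error(est, truth, _weights_for(s)) == 0.0

    def test_uniform_offset(self):
        s, est, truth = self._setup([1.0] * 8)
        assert mean_displacement_error(est, truth, _weights_for(s)) == \
            pytest.approx(1.0)

    def test_outliers_excluded(self):
        s, est, truth = self._setup([0.0] * 7 + [50.0])
        ws = _weights_for(s, outlier_ts={7})
        assert mean_displacement_error(est, truth, ws) == 0.0


class TestInterpolationTrend:
    def test_error_grows_with_tr_under_ideal_anchors(self):
        """With ground-truth low-b poses, the interpolation error of the
        breathing sine increases as samples per cycle drop (TR grows)."""
        errors = []
        for tr in (3.0, 6.0, 9.0, 12.0):
            geo = sch.AcquisitionGeometry(n_slices=30, tr=tr)
            s = sch.build_schedule(sch.make_superblock_scheme(25, 2), geo, L=2)
            trace = ph.breathing_trace(tr, 30, 50)
            ws = _weights_for(s)
            low = {tag.t: trace.transforms[tag.t].inverse()
                   for tag in s.low_b_tags()}
            series = assign_transforms(s, low, ws)
            errors.append(mean_displacement_error(series, trace, ws))
        assert errors == sorted(errors)
        assert errors[0] < 0.05

    def test_corrupted_outlier_anchor_does_not_leak(self):
        """A corrupted low-b pose flagged as outlier yields exactly the same
        interpolated series as removing that anchor altogether."""
        tr, ns, nv = 6.0, 12, 6
        geo = sch.AcquisitionGeometry(n_slices=ns, tr=tr)
        s = sch.build_schedule(sch.make_superblock_scheme(nv // 2, 2), geo, L=2)
        trace = ph.breathing_trace(tr, ns, nv)
        low_tags = s.low_b_tags()
        bad = low_tags[len(low_tags) // 2]
        low = {tag.t: trace.transforms[tag.t].inverse() for tag in low_tags}
        corrupted = dict(low)
        corrupted[bad.t] = RigidTransform.from_translation([0, 99.0, 0])
        ws_flag = _weights_for(s, outlier_ts={bad.t})
        with_flag = assign_transforms(s, corrupted, ws_flag)
        removed = dict(low)
        del removed[bad.t]
        without = assign_transforms(s, removed, ws_flag)
        for a, b in zip(with_flag, without):
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)


class TestSvrLowB:
    def test_motion_free_dataset_gives_identity(self, small_phantom):
        geo = sch.AcquisitionGeometry(n_slices=12, tr=3.0)
        s = sch.build_schedule(sch.make_superblock_scheme(3, 2), geo, L=2)
        ds = ph.acquire(small_phantom, s)
        target, transforms, weights = svr_low_b(ds, n_iterations=1)
        wmap = {w.tag.t: w for w in weights}
        offs = [np.abs(T.translation).max() for t, T in transforms.items()
                if not wmap[t].outlier]
        assert np.mean(offs) < 0.05

    def test_insufficient_low_b_rejected(self, small_phantom):
        geo = sch.AcquisitionGeometry(n_slices=12, tr=3.0)
        s = sch.build_schedule(sch.make_superblock_scheme(1, 2), geo, L=2)
        ds = ph.acquire(small_phantom, s)
        with pytest.raises(ValueError):
            svr_low_b(ds)
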