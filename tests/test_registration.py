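"""Rigid registration: known-shift/transform recovery, resampling round
trips and Lagrangian accumulation."""

import numpy as np
import pytest

import roboulm as r
from roboulm.registration import (
    RigidTransform,
    estimate_rigid_lm,
    estimate_translation,
    lagrangian_accumulate,
    resample,
)
from roboulm.imaging import _render_points

from conftest import speckle_volume


@pytest.fixture(scope="module")
def grid04():
    return r.VolumeGrid.centered((0.0, 0.0, 20.0), 12.4, 0.4)


@pytest.fixture(scope="module")
def grid01():
    return r.VolumeGrid.centered((0.0, 0.0, 20.0), 3.6, 0.1)


def rendered_pair(grid, seed, transform=None, shift=None, n=250, margin=2.0):
    """Reference plus a moving volume rendered from displaced scatterers."""
    probe = r.ProbeModel()
    psf = r.default_psf(probe)
    g = np.random.default_rng(seed)
    lo = grid.origin - margin
    hi = grid.origin + grid.extent_mm + margin
    pos = g.uniform(lo, hi, size=(n, 3))
    amp = g.rayleigh(1.0, size=n)
    ref = r.Volume(_render_points(pos, amp, probe, grid, psf), grid)
    if transform is not None:
        pos2 = transform.apply(pos)
    else:
        pos2 = pos + np.asarray(shift, float)
    mov = r.Volume(_render_points(pos2, amp, probe, grid, psf), grid)
    return ref, mov


class TestRigidTransform:
    def test_inverse_composition_is_identity(self):
        tr = RigidTransform(translation=[1.0, -2.0, 0.5],
                            rotation_deg=[3.0, -4.0, 5.0],
                            center=[0.0, 1.0, 20.0])
        pts = np.random.default_rng(0).uniform(-5, 5, size=(20, 3))
        back = tr.inverse().apply(tr.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)


class TestTranslationEstimate:
    def test_identity_case(self, grid04):
        ref, mov = rendered_pair(grid04, seed=1, shift=(0, 0, 0))
        res = estimate_translation(ref, mov)
        assert np.all(np.abs(res.transform.translation) < 0.01)

    def test_known_subvoxel_shift_recovery(self, grid04):
        shift = np.array([1.2, -0.8, 0.4])
        ref, mov = rendered_pair(grid04, seed=2, shift=shift)
        res = estimate_translation(ref, mov)
        # within 0.1 voxel at 0.4 mm pitch
        assert np.all(np.abs(res.transform.translation - shift) < 0.04)

    def test_large_shift_needs_pyramid(self):
        grid = r.VolumeGrid.centered((0.0, 0.0, 20.0), 24.8, 0.4)
        shift = np.array([5.0, 0.0, 0.0])
        ref, mov = rendered_pair(grid, seed=3, shift=shift, margin=8.0, n=900)
        single = estimate_translation(ref, mov, n_pyramid_levels=1)
        multi = estimate_translation(ref, mov, n_pyramid_levels=3)
        err_single = np.linalg.norm(single.transform.translation - shift)
        err_multi = np.linalg.norm(multi.transform.translation - shift)
        assert err_multi < 0.1
        assert err_single > 1.0

    def test_agreement_with_simpleitk_oracle(self, grid04):
        # independent cross-check: SimpleITK translation registration
        sitk = pytest.importorskip("SimpleITK")
        shift = np.array([0.9, -0.7, 0.5])
        ref, mov = rendered_pair(grid04, seed=21, shift=shift)
        ours = estimate_translation(ref, mov).transform.translation

        def to_sitk(vol):
            img = sitk.GetImageFromArray(np.ascontiguousarray(
                vol.data.astype(np.float32).transpose(2, 1, 0)))
            img.SetSpacing(tuple(float(p) for p in vol.grid.pitch))
            return img

        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-4, numberOfIterations=200,
            gradientMagnitudeTolerance=1e-10)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetInitialTransform(sitk.TranslationTransform(3), inPlace=False)
        reg.SetShrinkFactorsPerLevel([4, 2, 1])
        reg.SetSmoothingSigmasPerLevel([2, 1, 0])
        reg.SetInterpolator(sitk.sitkLinear)
        out = reg.Execute(to_sitk(ref), to_sitk(mov))
        theirs = np.array(out.GetParameters())  # (x, y, z) physical offsets
        np.testing.assert_allclose(ours, theirs, atol=0.05)
        np.testing.assert_allclose(theirs, shift, atol=0.1)

    def test_flat_volume_flagged(self, grid04):
        flat = r.Volume(np.zeros(grid04.shape), grid04)
        res = estimate_translation(flat, flat)
        assert not res.converged


class TestRigidLM:
    def test_truth_init_keeps_cost(self, grid01):
        tr = RigidTransform(translation=[0.5, -0.3, 0.2],
                            rotation_deg=[1.0, 2.0, -1.5],
                            center=grid01.center)
        ref, mov = rendered_pair(grid01, seed=4, transform=tr)
        res = estimate_rigid_lm(ref, mov, init=tr)
        assert res.converged
        assert np.all(np.abs(res.transform.translation - tr.translation) < 0.02)

    def test_known_transform_recovery(self, grid01):
        tr = RigidTransform(translation=[0.8, -0.5, 0.3],
                            rotation_deg=[1.5, -2.0, 2.5],
                            center=grid01.center)
        ref, mov = rendered_pair(grid01, seed=5, transform=tr)
        res = estimate_rigid_lm(ref, mov)
        assert np.all(np.abs(res.transform.translation - tr.translation) < 0.05)
        assert np.all(np.abs(res.transform.rotation_deg - tr.rotation_deg) < 0.1)

    def test_warm_start_reduces_iterations(self, grid01):
        # smooth motion sequence: warm start from the previous frame's result
        steps = [RigidTransform(translation=[0.3 * k, 0.1 * k, 0.0],
                                rotation_deg=[0.0, 0.0, 0.5 * k],
                                center=grid01.center) for k in range(1, 4)]
        ref, _ = rendered_pair(grid01, seed=6)
        cold_iters = warm_iters = 0
        prev = None
        for tr in steps:
            _, mov = rendered_pair(grid01, seed=6, transform=tr)
            cold = estimate_rigid_lm(ref, mov)
            warm = estimate_rigid_lm(ref, mov, init=prev)
            cold_iters += cold.n_iterations
            warm_iters += warm.n_iterations
            prev = warm.transform
        assert warm_iters < cold_iters

    def test_agreement_with_translation_estimator(self, grid04):
        shift = np.array([0.9, -0.6, 0.3])
        ref, mov = rendered_pair(grid04, seed=7, shift=shift)
        fast = estimate_translation(ref, mov)
        full = estimate_rigid_lm(
            ref, mov, init=RigidTransform(translation=fast.transform.translation,
                                          center=grid04.center))
        assert np.all(np.abs(full.transform.translation
                             - fast.transform.translation) < 0.05)

    def test_ssd_at_estimate_not_worse_than_truth(self, grid01):
        tr = RigidTransform(translation=[0.4, 0.2, -0.3],
                            rotation_deg=[1.0, -1.0, 0.5],
                            center=grid01.center)
        ref, mov = rendered_pair(grid01, seed=8, transform=tr)
        res = estimate_rigid_lm(ref, mov, init=tr)
        # evaluate SSD of the smoothed problem at truth with the same machinery
        truth_res = estimate_rigid_lm(ref, mov, init=tr, max_iterations=1)
        assert res.final_cost <= truth_res.final_cost + 1e-6


class TestResample:
    def test_identity_is_exact(self, grid04):
        ref, _ = rendered_pair(grid04, seed=9)
        out, mask = resample(ref, RigidTransform(center=grid04.center))
        np.testing.assert_allclose(out.data, ref.data, atol=1e-12)
        assert mask.all()

    def test_integer_voxel_shift_equals_index_shift(self, grid04):
        ref, _ = rendered_pair(grid04, seed=10)
        shift = np.array([2, 0, -1]) * grid04.pitch
        out, mask = resample(ref, RigidTransform(translation=shift,
                                                 center=grid04.center))
        expected = np.roll(ref.data, (-2, 0, 1), axis=(0, 1, 2))
        core = (slice(3, -3),) * 3
        np.testing.assert_allclose(out.data[core], expected[core], atol=1e-12)

    def test_shift_roundtrip_recovers_interior(self):
        # well-sampled volume (PSF FWHM ~ 8 voxels at 0.05 mm pitch)
        grid = r.VolumeGrid.centered((0.0, 0.0, 20.0), 3.2, 0.05)
        ref, _ = rendered_pair(grid, seed=11, n=120, margin=1.0)
        tr = RigidTransform(translation=[0.27, -0.13, 0.21], center=grid.center)
        fwd, _ = resample(ref, tr)
        back, mask = resample(fwd, tr.inverse())
        core = (slice(10, -10),) * 3
        err = np.abs(back.data[core] - ref.data[core]).max()
        assert err < 1e-3 * ref.data.max()


class TestLagrangianAccumulate:
    def _point_frames(self, grid, n_frames=5, step=(0.4, 0.0, 0.0)):
        probe = r.ProbeModel()
        psf = r.default_psf(probe)
        frames, transforms = [], []
        for k in range(n_frames):
            shift = np.asarray(step) * k
            pos = np.array([[0.0, 0.0, 20.0]]) + shift
            frames.append(r.Volume(
                _render_points(pos, np.array([10.0]), probe, grid, psf), grid))
            transforms.append(RigidTransform(translation=shift))
        return frames, transforms

    def test_identity_mean_is_temporal_mean(self, grid04):
        frames = [rendered_pair(grid04, seed=s)[0] for s in (12, 13, 14)]
        identity = [RigidTransform() for _ in frames]
        out, counts = lagrangian_accumulate(frames, identity, reducer="mean")
        expected = np.mean([f.data for f in frames], axis=0)
        np.testing.assert_allclose(out.data, expected, atol=1e-9)

    def test_exact_transforms_concentrate_moving_point(self):
        grid = r.VolumeGrid.centered((0.0, 0.0, 20.0), 8.0, 0.2)
        frames, transforms = self._point_frames(grid)
        corrected, _ = lagrangian_accumulate(frames, transforms, reducer="mean")
        smeared, _ = lagrangian_accumulate(
            frames, [RigidTransform() for _ in frames], reducer="mean")

        def spread(data):
            idx = np.stack(np.meshgrid(*[np.arange(n) for n in data.shape],
                                       indexing="ij"))
            w = data / data.sum()
            mu = [(idx[i] * w).sum() for i in range(3)]
            return sum(((idx[i] - mu[i]) ** 2 * w).sum() for i in range(3))

        # motion-corrected accumulation is a single stationary blob; the
        # uncorrected one smears along the motion (positive control)
        assert spread(corrected.data) < 0.5 * spread(smeared.data)

    def test_mismatched_counts_rejected(self, grid04):
        ref, _ = rendered_pair(grid04, seed=15)
        with pytest.raises(ValueError):
            lagrangian_accumulate([ref], [], reducer="mean")
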