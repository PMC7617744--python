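"""ULM chain: noise suppression, PSF estimation, NCC localisation,
track linking, persistence and map accumulation/smoothing."""

import numpy as np
import pytest
from dataclasses import replace

import roboulm as r
from roboulm.imaging import _render_points
from roboulm.ulm import (
    Localisation,
    PSFTemplate,
    Track,
    accumulate_maps,
    estimate_psf,
    link_tracks,
    localise,
    ncc_map,
    persistence_filter,
    smooth_maps,
    suppress_background,
)


@pytest.fixture(scope="module")
def probe01():
    return r.ProbeModel()


@pytest.fixture(scope="module")
def psf01(probe01):
    return r.default_psf(probe01)


@pytest.fixture(scope="module")
def grid01():
    # odd shape so a voxel centre sits exactly at the grid centre
    return r.VolumeGrid.centered((0.0, 0.0, 20.0), 4.1, 0.1)


def bubble_volume(grid, positions, amps=None, probe=None, psf=None, noise=0.0,
                  seed=0):
    probe = probe or r.ProbeModel()
    psf = psf or r.default_psf(probe)
    positions = np.atleast_2d(positions)
    amps = np.full(len(positions), 10.0) if amps is None else np.atleast_1d(amps)
    data = _render_points(positions, amps, probe, grid, psf)
    if noise > 0:
        data = data + np.random.default_rng(seed).normal(0, noise, data.shape)
    return r.Volume(data=data, grid=grid)


def gaussian_template(grid_pitch=0.1, psf=None, half=4):
    psf = psf or r.default_psf(r.ProbeModel())
    ax = np.arange(-half, half + 1) * grid_pitch
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    s = psf.sigma_mm
    t = np.exp(-0.5 * ((gx / s[0]) ** 2 + (gy / s[1]) ** 2 + (gz / s[2]) ** 2))
    return PSFTemplate(data=t / t.max(), pitch_mm=grid_pitch)


class TestSuppressBackground:
    def test_all_zero_stays_zero(self, grid01):
        vol = r.Volume(np.zeros(grid01.shape), grid01)
        out = suppress_background(vol, noise_floor=0.1)
        assert out.data.max() == 0.0

    def test_isolated_bright_voxel_kept(self, grid01):
        data = np.zeros(grid01.shape)
        data[20, 20, 20] = 5.0
        out = suppress_background(r.Volume(data, grid01), noise_floor=1.0)
        assert out.data[20, 20, 20] == 5.0
        assert out.data.sum() == 5.0

    def test_uniform_volume_fully_suppressed(self, grid01):
        # every voxel equals its local mean -> strict threshold removes all
        vol = r.Volume(np.full(grid01.shape, 2.0), grid01)
        out = suppress_background(vol, noise_floor=2.0)
        assert out.data.max() == 0.0

    def test_hand_computed_three_cube(self):
        # 3^3 grid: centre above neighbours survives, neighbours do not
        g = r.VolumeGrid(origin=(0, 0, 0), pitch=0.1, shape=(5, 5, 5))
        data = np.ones((5, 5, 5))
        data[2, 2, 2] = 10.0
        out = suppress_background(r.Volume(data, g), noise_floor=0.5,
                                  kernel_size=3)
        assert out.data[2, 2, 2] == 10.0
        assert out.data[1, 1, 1] == 0.0


class TestEstimatePSF:
    def test_identical_patches_returned_unit_peak(self, grid01, psf01):
        g = r.VolumeGrid.centered((0, 0, 20), 0.9, 0.1)
        patch = bubble_volume(g, [0.0, 0.0, 20.0], psf=psf01)
        tpl = estimate_psf([patch] * 5)
        assert tpl.data.max() == pytest.approx(1.0)
        ref = patch.data / patch.data.max()
        assert np.max(np.abs(tpl.data - ref)) < 0.02

    def test_noisy_copies_recover_fwhm(self, psf01):
        g = r.VolumeGrid.centered((0, 0, 20), 1.3, 0.1)
        patches = [bubble_volume(g, [0.0, 0.0, 20.0], psf=psf01, noise=0.2,
                                 seed=s) for s in range(5)]
        tpl = estimate_psf(patches)
        # measured FWHM along the axial profile (interpolated) within 10%
        prof = tpl.data[6, 6, :]
        fine_x = np.linspace(0, len(prof) - 1, 5001)
        fine = np.interp(fine_x, np.arange(len(prof)), prof)
        above = fine_x[fine >= 0.5 * fine.max()]
        fwhm = (above[-1] - above[0]) * 0.1
        assert fwhm == pytest.approx(psf01.fwhm_mm[2], rel=0.10)

    def test_subvoxel_offsets_broaden_at_most_offset(self, psf01):
        g = r.VolumeGrid.centered((0, 0, 20), 1.3, 0.1)
        offset = 0.04
        patches = [bubble_volume(g, [dx, 0.0, 20.0], psf=psf01)
                   for dx in (-offset, 0.0, offset)]
        tpl = estimate_psf(patches)
        clean = bubble_volume(g, [0.0, 0.0, 20.0], psf=psf01)

        def fwhm_x(d):
            prof = d[:, 6, 6]
            fine = np.interp(np.linspace(0, len(prof) - 1, 1001),
                             np.arange(len(prof)), prof)
            above = np.flatnonzero(fine >= 0.5 * fine.max())
            return (above[-1] - above[0]) / 1000 * (len(prof) - 1) * 0.1

        assert fwhm_x(tpl.data) <= fwhm_x(clean.data) + offset

    def test_single_patch_needs_flag(self, grid01):
        patch = bubble_volume(grid01, [0.0, 0.0, 20.0])
        with pytest.raises(ValueError):
            estimate_psf([patch])
        tpl = estimate_psf([patch], allow_single=True)
        assert tpl.data.max() == pytest.approx(1.0)


class TestNCCMap:
    def test_template_matches_score_one(self, grid01, psf01):
        vol = bubble_volume(grid01, [0.0, 0.0, 20.0], psf=psf01)
        tpl = gaussian_template(0.1, psf01)
        scores = ncc_map(vol, tpl)
        assert scores.data.max() == pytest.approx(1.0, abs=1e-3)

    def test_anticorrelated_patch_scores_minus_one(self, psf01):
        g = r.VolumeGrid(origin=(0, 0, 0), pitch=0.1, shape=(24, 24, 24))
        tpl = gaussian_template(0.1, psf01, half=3)
        data = np.zeros(g.shape)
        data[8:15, 8:15, 8:15] = -(tpl.data + 0.0)
        scores = ncc_map(r.Volume(data, g), tpl)
        assert scores.data.min() == pytest.approx(-1.0, abs=1e-3)

    def test_matches_bruteforce_pearson(self, psf01):
        # direct per-voxel Pearson correlation oracle on a 16^3 volume
        rng = np.random.default_rng(5)
        g = r.VolumeGrid(origin=(0, 0, 0), pitch=0.1, shape=(16, 16, 16))
        vol = r.Volume(rng.normal(size=g.shape), g)
        tpl_data = rng.normal(size=(5, 5, 5))
        tpl_data -= tpl_data.min()
        tpl = PSFTemplate(tpl_data / tpl_data.max(), 0.1)
        scores = ncc_map(vol, tpl)
        t = tpl.data - tpl.data.mean()
        for idx in [(8, 8, 8), (5, 10, 7), (10, 4, 11)]:
            sl = tuple(slice(i - 2, i + 3) for i in idx)
            w = vol.data[sl] - vol.data[sl].mean()
            expected = float((w * t).sum()
                             / np.sqrt((w**2).sum() * (t**2).sum()))
            assert scores.data[idx] == pytest.approx(expected, abs=1e-6)

    def test_zero_variance_template_rejected(self, grid01):
        vol = r.Volume(np.zeros(grid01.shape), grid01)
        with pytest.raises(ValueError):
            ncc_map(vol, PSFTemplate(np.ones((5, 5, 5)), 0.1))


class TestLocalise:
    def test_voxel_centre_bubble(self, grid01, psf01):
        pos = grid01.index_to_mm((20, 20, 20))
        vol = bubble_volume(grid01, pos, psf=psf01)
        scores = ncc_map(vol, gaussian_template(0.1, psf01))
        locs = localise(scores, vol)
        assert len(locs) == 1
        np.testing.assert_allclose(locs[0].position_mm, pos, atol=0.2 / 5 * 0.1)

    def test_subvoxel_sweep_error_below_pitch_over_upsample(self, grid01, psf01):
        tpl = gaussian_template(0.1, psf01)
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(30):
            true = np.array([0.0, 0.0, 20.0]) + rng.uniform(-0.05, 0.05, 3)
            vol = bubble_volume(grid01, true, psf=psf01)
            scores = ncc_map(vol, tpl)
            locs = localise(scores, vol)
            assert len(locs) == 1
            errs.append(np.linalg.norm(locs[0].position_mm - true))
        assert np.mean(errs) < 0.1 / 5  # pitch / upsample

    def test_below_threshold_empty(self, grid01, psf01):
        rng = np.random.default_rng(8)
        vol = r.Volume(rng.normal(0, 1.0, grid01.shape), grid01)
        scores = ncc_map(vol, gaussian_template(0.1, psf01))
        assert scores.data.max() < 0.5  # noise does not resemble the PSF
        assert localise(scores, vol) == []

    def test_well_separated_pair_both_found(self, grid01, psf01):
        pos = np.array([[-1.0, 0.0, 19.5], [1.0, 0.0, 20.5]])
        vol = bubble_volume(grid01, pos, psf=psf01)
        scores = ncc_map(vol, gaussian_template(0.1, psf01))
        locs = localise(scores, vol)
        assert len(locs) == 2


class TestLinking:
    def _loc(self, p, f):
        return Localisation(np.asarray(p, float), f, 0.9, 1.0)

    def test_single_moving_bubble_single_track(self):
        per_frame = [[self._loc([0.1 * k, 0.0, 20.0], k)] for k in range(10)]
        tracks = link_tracks(per_frame, volume_rate_hz=20.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10
        # per-step speed = step distance x rate
        np.testing.assert_allclose(tracks[0].speeds_mm_s, 0.1 * 20.0)

    def test_parallel_bubbles_no_identity_switch(self):
        per_frame = []
        for k in range(50):
            per_frame.append([
                self._loc([0.05 * k, 0.0, 20.0], k),
                self._loc([0.05 * k, 0.15, 20.0], k),  # 3x the per-frame step
            ])
        tracks = link_tracks(per_frame, volume_rate_hz=20.0)
        assert len(tracks) == 2
        for tr in tracks:
            ys = tr.positions_mm[:, 1]
            assert np.ptp(ys) < 1e-9  # each track stays in its lane

    def test_crossing_tracks_resolved_by_prediction(self):
        rng = np.random.default_rng(11)
        good = 0
        n_trials = 40
        for _ in range(n_trials):
            jitter = rng.normal(0, 0.002, size=(2, 20, 2))
            per_frame = []
            for k in range(20):
                # two bubbles crossing in x at frame ~10
                a = [-0.5 + 0.05 * k + jitter[0, k, 0],
                     0.0 + jitter[0, k, 1], 20.0]
                b = [0.5 - 0.05 * k + jitter[1, k, 0],
                     0.0 + jitter[1, k, 1], 20.0]
                per_frame.append([self._loc(a, k), self._loc(b, k)])
            tracks = link_tracks(per_frame, volume_rate_hz=20.0,
                                 max_speed_mm_s=2.0)
            if len(tracks) == 2:
                slopes = [np.polyfit(tr.frames, tr.positions_mm[:, 0], 1)[0]
                          for tr in tracks]
                if np.sign(slopes[0]) != np.sign(slopes[1]):
                    good += 1
        assert good / n_trials >= 0.9

    def test_gate_prevents_impossible_jumps(self):
        per_frame = [[self._loc([0.0, 0.0, 20.0], 0)],
                     [self._loc([5.0, 0.0, 20.0], 1)]]
        tracks = link_tracks(per_frame, volume_rate_hz=20.0,
                             max_speed_mm_s=10.0)
        assert len(tracks) == 2  # 100 mm/s apparent speed exceeds the gate


class TestPersistence:
    def _track_of_length(self, n):
        return Track(frames=list(range(n)),
                     positions_mm=np.zeros((n, 3)),
                     scores=[1.0] * n).finalise(20.0)

    def test_threshold_four_frames(self):
        tracks = [self._track_of_length(n) for n in (1, 3, 4, 7)]
        kept = persistence_filter(tracks, min_frames=4)
        assert sorted(len(t) for t in kept) == [4, 7]

    def test_min_one_is_identity(self):
        tracks = [self._track_of_length(n) for n in (1, 2, 5)]
        assert len(persistence_filter(tracks, min_frames=1)) == 3

    def test_removed_count_matches_bruteforce(self, rng):
        lengths = rng.integers(1, 10, size=30)
        tracks = [self._track_of_length(int(n)) for n in lengths]
        kept = persistence_filter(tracks, min_frames=4)
        assert len(tracks) - len(kept) == int(np.sum(lengths < 4))


@pytest.fixture(scope="module")
def map_grid():
    return r.VolumeGrid.centered((0.0, 0.0, 20.0), (2.0, 1.0, 1.0), 0.02)


class TestMaps:
    def _straight_track(self, y=0.0, z=20.0, speed=1.0, n=10, rate=20.0,
                        half_span=0.8):
        # per-step speed = step x rate; choose the step to set the speed
        step = speed / rate
        xs = -half_span + step * np.arange(n)
        pos = np.column_stack([xs, np.full(n, y), np.full(n, z)])
        tr = Track(frames=list(range(n)), positions_mm=pos, scores=[1.0] * n)
        return tr.finalise(rate)

    def test_single_track_density_one(self, map_grid):
        maps = accumulate_maps([self._straight_track(n=30)], map_grid, 20.0)
        assert maps.density.data.max() == 1.0
        assert maps.density.data.sum() > 50  # covers the path

    def test_colinear_tracks_density_two(self, map_grid):
        t1 = self._straight_track()
        t2 = self._straight_track()
        maps = accumulate_maps([t1, t2], map_grid, 20.0)
        assert maps.density.data.max() == 2.0

    def test_speed_map_poiseuille_profile(self, map_grid):
        # Poiseuille: centreline speed 2x the mean; near-wall well below.
        # Tracks sampled from the parabolic profile v(r) = 2 vbar (1-(r/R)^2).
        rate = 50.0
        vbar, R = 1.0, 0.4
        tracks = []
        for r_off in (0.0, 0.35):
            v = 2.0 * vbar * (1.0 - (r_off / R) ** 2)
            tracks.append(self._straight_track(y=r_off, speed=v, n=30,
                                               rate=rate))
        maps = accumulate_maps(tracks, map_grid, rate)
        sp = maps.speed.data
        iy_c = int(round(maps.speed.grid.mm_to_index([0.0, 0.0, 20.0])[1]))
        iy_w = int(round(maps.speed.grid.mm_to_index([0.0, 0.35, 20.0])[1]))
        center = sp[:, iy_c, :][sp[:, iy_c, :] > 0]
        wall = sp[:, iy_w, :][sp[:, iy_w, :] > 0]
        true_ratio = 2.0 / (2.0 * (1.0 - (0.35 / R) ** 2))
        assert center.mean() / wall.mean() == pytest.approx(true_ratio, rel=0.2)

    def test_gaussian_smoothing_fwhm_and_mass(self, map_grid):
        delta = np.zeros(map_grid.shape)
        delta[50, 25, 25] = 1.0
        maps = r.ULMMaps(r.Volume(delta, map_grid),
                         r.Volume(np.zeros(map_grid.shape), map_grid))
        sm = smooth_maps(maps)
        # mass conserved
        assert sm.density.data.sum() == pytest.approx(1.0, rel=1e-3)
        prof = sm.density.data[:, 25, 25]
        fine_x = np.linspace(0, len(prof) - 1, 5001)
        fine = np.interp(fine_x, np.arange(len(prof)), prof)
        above = fine_x[fine >= 0.5 * fine.max()]
        fwhm_um = (above[-1] - above[0]) * 0.02 * 1000
        assert fwhm_um == pytest.approx(40.0, abs=4.0)

    def test_uniform_speed_unchanged_by_ball_filter(self, map_grid):
        density = np.ones(map_grid.shape)
        speed = np.full(map_grid.shape, 3.0)
        sm = smooth_maps(r.ULMMaps(r.Volume(density, map_grid),
                                   r.Volume(speed, map_grid)))
        core = (slice(3, -3),) * 3
        np.testing.assert_allclose(sm.speed.data[core], 3.0, atol=1e-9)
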