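"""3D nuclei pipeline: deconvolution, alignment, detection, segmentation."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from spheroquant import nuclei as nuc
from spheroquant import synth
from spheroquant.errors import NoSpheroidError, ValidationError
from spheroquant.nuclei import (ImageStack3D, NucleiParams,
                                NucleiSegmentation, align_z, count_nuclei,
                                denoise, detect_spots3d, gaussian_psf,
                                grow_regions, nuclei_density, optical_density,
                                quantify, richardson_lucy, separate_objects,
                                smooth_labels, spheroid_volume)

ISO = (1.0, 1.0, 1.0)


def _blob_stack(centers, sigma=2.0, shape=(40, 40, 40), amp=1.0, bg=0.02):
    vox = np.full(shape, bg)
    zz, yy, xx = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]]
    for c in centers:
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        vox += amp * np.exp(-0.5 * d2 / sigma**2)
    return ImageStack3D(vox, ISO)


class TestRichardsonLucy:
    def test_delta_psf_is_identity(self, rng):
        stack = ImageStack3D(rng.uniform(0.1, 1.0, (6, 12, 12)), ISO)
        psf = np.zeros((3, 3, 3))
        psf[1, 1, 1] = 1.0
        out = richardson_lucy(stack, psf, iterations=5)
        assert np.allclose(out.voxels, stack.voxels, rtol=1e-8)

    def test_sharpens_blurred_blobs(self):
        truth = _blob_stack([(20, 14, 14), (20, 26, 26)], sigma=2.0)
        psf = gaussian_psf((1.5, 1.5, 1.5), ISO)
        blurred = ndi.convolve(truth.voxels, psf, mode="nearest")
        stack = ImageStack3D(blurred, ISO)
        out = richardson_lucy(stack, psf, iterations=20)
        mid = out.voxels[20]
        peak = mid[14, 14]
        valley = mid[20, 20]
        peak_b, valley_b = blurred[20, 14, 14], blurred[20, 20, 20]
        assert peak / valley > peak_b / valley_b  # contrast strictly increases

    def test_conserves_intensity_and_nonnegativity(self, rng):
        stack = ImageStack3D(rng.uniform(0.0, 1.0, (8, 16, 16)), ISO)
        psf = gaussian_psf((1.0, 1.0, 1.0), ISO)
        out = richardson_lucy(stack, psf, iterations=10)
        assert np.all(out.voxels >= 0)
        assert out.voxels.sum() == pytest.approx(stack.voxels.sum(), rel=0.01)

    def test_invalid_inputs_rejected(self, rng):
        stack = ImageStack3D(rng.uniform(0.1, 1.0, (6, 12, 12)), ISO)
        with pytest.raises(ValidationError):
            richardson_lucy(stack, np.ones((3, 3, 3)), iterations=5)
        bad = ImageStack3D(stack.voxels - 0.5, ISO)
        with pytest.raises(ValidationError):
            richardson_lucy(bad, gaussian_psf((1.0, 1.0, 1.0), ISO))


class TestAlignZ:
    def test_aligned_stack_keeps_zero_shifts(self):
        stack = _blob_stack([(z, 20, 20) for z in range(8, 32, 6)])
        _out, shifts, _lc = align_z(stack)
        assert np.allclose(shifts, 0.0, atol=0.3)

    def test_recovers_injected_shifts(self, rng):
        # z-correlated texture so every slice pair shares structure
        base = ndi.gaussian_filter(rng.uniform(0, 1, (20, 48, 48)),
                                   sigma=(6.0, 1.0, 1.0))
        true_steps = rng.uniform(-2, 2, size=(20, 2))
        true_steps[0] = 0
        cum = np.cumsum(true_steps, axis=0)
        shifted = np.array([ndi.shift(sl, -cum[i], order=1, mode="nearest")
                            for i, sl in enumerate(base)])
        _out, shifts, _lc = align_z(ImageStack3D(shifted, ISO))
        # recovered cumulative shifts undo the injected drift
        err = shifts - cum
        err -= err.mean(axis=0)
        assert np.abs(err[3:-3]).max() < 0.5

    def test_pure_noise_flagged_and_bounded(self, rng):
        stack = ImageStack3D(rng.uniform(0, 1, (10, 32, 32)), ISO)
        _out, shifts, low_conf = align_z(stack, max_shift_px=5.0)
        assert np.abs(shifts).max() <= 5.0 * len(shifts)
        assert low_conf.any()


class TestDenoise:
    def test_zero_sigma_identity(self, rng):
        stack = ImageStack3D(rng.uniform(0, 1, (6, 10, 10)), ISO)
        assert denoise(stack, 0.0) is stack

    def test_reduces_checkerboard_variance(self):
        vox = np.indices((6, 12, 12)).sum(axis=0) % 2.0
        stack = ImageStack3D(vox, ISO)
        out = denoise(stack, 1.0)
        assert out.voxels.var() < stack.voxels.var()

    def test_anisotropic_voxels_get_anisotropic_kernel(self):
        # a physical sigma of 1 um is 2 voxels laterally but 0.5 axially here
        vox = np.zeros((11, 21, 21))
        vox[5, 10, 10] = 1.0
        out = denoise(ImageStack3D(vox, (2.0, 0.5, 0.5)), 1.0)
        profile_z = out.voxels[:, 10, 10]
        profile_y = out.voxels[5, :, 10]
        assert profile_z[6] / profile_z[5] < profile_y[12] / profile_y[10]


class TestDetectSpots:
    def test_well_separated_nuclei_found_exactly(self):
        stack, _bf, truth = synth.gen_nuclei_stack(
            synth.StackScenario(n_nuclei=50), seed=0)
        seeds = detect_spots3d(denoise(stack, 0.5), nucleus_diameter_um=4.0)
        assert len(seeds) == 50
        d = np.linalg.norm(
            (seeds[:, None, :] - truth.centers_vox[None, :, :])
            * np.array(stack.voxel_size), axis=2)
        assert (d.min(axis=1) <= 1.5).all()  # within ~1 voxel physically

    def test_empty_stack_yields_no_seeds(self):
        stack = ImageStack3D(np.zeros((6, 20, 20)), ISO)
        assert len(detect_spots3d(stack, 4.0)) == 0

    def test_close_pair_never_over_segmented(self):
        stack = _blob_stack([(20, 20, 18), (20, 20, 22)], sigma=2.0)
        seeds = detect_spots3d(stack, nucleus_diameter_um=8.0)
        assert 1 <= len(seeds) <= 2


class TestGrowRegions:
    def test_single_nucleus_grows_to_margin(self):
        # plateau ball with a soft edge: Otsu cuts mid-edge, so the grown
        # label volume tracks the true ball volume
        radius = 8.0
        zz, yy, xx = np.mgrid[0:40, 0:40, 0:40]
        ball = ((zz - 20.0) ** 2 + (yy - 20.0) ** 2
                + (xx - 20.0) ** 2 <= radius**2).astype(float)
        stack = ImageStack3D(ndi.gaussian_filter(ball, 1.0) + 0.02, ISO)
        seg = grow_regions(stack, np.array([[20, 20, 20]]),
                           smooth_sigma_um=0.0)
        vol = (seg.labels == 1).sum()
        assert vol == pytest.approx(4 / 3 * np.pi * radius**3, rel=0.2)

    def test_touching_nuclei_split_at_valley(self):
        stack = _blob_stack([(20, 20, 14), (20, 20, 26)], sigma=3.0)
        seeds = np.array([[20, 20, 14], [20, 20, 26]])
        seg = grow_regions(stack, seeds)
        assert seg.count == 2
        left = seg.labels[20, 20, 14]
        right = seg.labels[20, 20, 26]
        assert left != right and left > 0 and right > 0

    def test_no_seeds_rejected(self):
        stack = _blob_stack([(20, 20, 20)])
        with pytest.raises(ValidationError):
            grow_regions(stack, np.empty((0, 3), int))


class TestSmoothLabels:
    def _spiky(self):
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        labels[8:13, 8:13, 8:13] = 1
        labels[10, 10, 13:19] = 1  # 1-voxel spur
        return NucleiSegmentation(labels, np.array([[10, 10, 10]]), ISO)

    def test_zero_radius_identity(self):
        seg = self._spiky()
        assert smooth_labels(seg, 0.0) is seg

    def test_spur_removed(self):
        seg = smooth_labels(self._spiky(), radius_um=1.0)
        assert not seg.labels[10, 10, 15:19].any()
        assert seg.labels[10, 10, 10] == 1

    def test_count_never_increases(self):
        stack, _bf, _tr = synth.gen_nuclei_stack(
            synth.StackScenario(n_nuclei=30), seed=1)
        st = denoise(stack, 0.5)
        seeds = detect_spots3d(st, 4.0)
        seg = grow_regions(st, seeds)
        assert smooth_labels(seg).count <= seg.count


class TestSeparateObjects:
    def _dumbbell(self):
        labels = np.zeros((16, 24, 40), dtype=np.int32)
        zz, yy, xx = np.mgrid[0:16, 0:24, 0:40]
        ball1 = (zz - 8) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= 36
        ball2 = (zz - 8) ** 2 + (yy - 12) ** 2 + (xx - 28) ** 2 <= 36
        labels[ball1 | ball2] = 1
        labels[8, 12, 12:29] = 1  # thin lateral neck
        return NucleiSegmentation(labels, np.array([[8, 12, 12], [8, 12, 28]]),
                                  ISO)

    def test_dumbbell_split_in_two(self):
        seg = separate_objects(self._dumbbell(), erosion_count=2)
        assert seg.count == 2
        assert seg.labels[8, 12, 12] != seg.labels[8, 12, 28]

    def test_solid_ball_not_split(self):
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        zz, yy, xx = np.mgrid[0:20, 0:20, 0:20]
        labels[(zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2 <= 49] = 1
        seg = NucleiSegmentation(labels, np.array([[10, 10, 10]]), ISO)
        assert separate_objects(seg, 2).count == 1

    def test_zero_erosion_identity(self):
        seg = self._dumbbell()
        assert separate_objects(seg, 0) is seg


class TestCountingAndVolume:
    def test_empty_segmentation_counts_zero(self):
        seg = NucleiSegmentation(np.zeros((5, 5, 5), np.int32),
                                 np.empty((0, 3), int), ISO)
        assert count_nuclei(seg) == 0

    def test_min_volume_monotone(self):
        labels = np.zeros((10, 10, 10), np.int32)
        labels[1, 1, 1] = 1          # 1 um^3
        labels[4:6, 4:8, 4:8] = 2    # 32 um^3
        seg = NucleiSegmentation(labels, np.empty((0, 3), int), ISO)
        counts = [count_nuclei(seg, v) for v in (0.5, 5.0, 50.0)]
        assert counts == [2, 1, 0]

    def test_equivalent_sphere_formula(self):
        assert spheroid_volume(method="equivalent_sphere",
                               diameter_um=100.0) == pytest.approx(523598.8,
                                                                   rel=1e-6)

    def test_voxelized_ball_volume(self):
        zz, yy, xx = np.mgrid[0:70, 0:70, 0:70]
        ball = (zz - 35) ** 2 + (yy - 35) ** 2 + (xx - 35) ** 2 <= 30**2
        vol = spheroid_volume(ball, voxel_size=ISO)
        assert vol == pytest.approx(4 / 3 * np.pi * 30**3, rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(NoSpheroidError):
            spheroid_volume(np.zeros((5, 5, 5), bool), voxel_size=ISO)

    def test_density_ratio(self):
        assert nuclei_density(50, 523598.8) == pytest.approx(9.549e-5,
                                                             rel=1e-3)
        assert nuclei_density(0, 100.0) == 0.0
        with pytest.raises(ValidationError):
            nuclei_density(10, 0.0)


class TestOpticalDensity:
    def _disk_image(self, attenuation=0.1, area_um2=1000.0, i_bg=0.8):
        img = np.full((90, 90), i_bg)
        yy, xx = np.mgrid[0:90, 0:90]
        r = np.sqrt(area_um2 / np.pi)
        img[np.hypot(yy - 45, xx - 45) <= r] = i_bg * attenuation
        return img

    def test_flat_disk_closed_form(self):
        img = self._disk_image(attenuation=0.1)
        area_px = int((np.hypot(*np.mgrid[0:90, 0:90] - 45) <= np.sqrt(
            1000 / np.pi)).sum())
        od = optical_density(img, pixel_size=1.0)
        assert od == pytest.approx(1.0 / area_px, rel=0.02)

    def test_darker_disk_has_larger_od(self):
        od_light = optical_density(self._disk_image(0.3), 1.0)
        od_dark = optical_density(self._disk_image(0.05), 1.0)
        assert od_dark > od_light

    def test_uniform_image_rejected(self):
        with pytest.raises(NoSpheroidError, match="no_spheroid"):
            optical_density(np.full((50, 50), 0.8), 1.0)


class TestQuantify:
    def test_treated_vs_control_ordering(self):
        control = synth.StackScenario(n_nuclei=40, spheroid_radius_um=22.0)
        treated = synth.StackScenario(n_nuclei=30, spheroid_radius_um=15.0)
        params = NucleiParams(nucleus_diameter_um=4.0)
        sc, _bfc, _tc = synth.gen_nuclei_stack(control, seed=2)
        st, _bft, _tt = synth.gen_nuclei_stack(treated, seed=2)
        qc = quantify(sc, params=params)
        qt = quantify(st, params=params)
        assert qt.count < qc.count
        assert qt.density > qc.density

    def test_deterministic_on_identical_stacks(self):
        stack, bf, _tr = synth.gen_nuclei_stack(
            synth.StackScenario(n_nuclei=25), seed=4)
        params = NucleiParams(nucleus_diameter_um=4.0)
        q1 = quantify(stack, brightfield=bf, params=params)
        q2 = quantify(stack, brightfield=bf, params=params)
        assert (q1.count, q1.volume, q1.density) == (q2.count, q2.volume,
                                                     q2.density)
        assert q1.optical_density == q2.optical_density

    def test_density_identity_and_missing_brightfield(self):
        stack, _bf, _tr = synth.gen_nuclei_stack(
            synth.StackScenario(n_nuclei=25), seed=4)
        q = quantify(stack, params=NucleiParams(nucleus_diameter_um=4.0))
        assert q.density == q.count / q.volume
        assert q.optical_density is None

    def test_deconvolution_path_runs(self):
        stack, _bf, _tr = synth.gen_nuclei_stack(
            synth.StackScenario(n_nuclei=15), seed=6)
        params = NucleiParams(nucleus_diameter_um=4.0, deconvolve=True,
                              rl_iterations=5,
                              psf_sigma_um=(0.75, 0.3, 0.3))
        q = quantify(stack, params=params)
        assert abs(q.count - 15) <= 2
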