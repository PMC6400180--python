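"""Synthetic-data generator: geometry, physics oracles, reproducibility."""

import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from spisort.containers import DensityMap, point_reflect
from spisort.metrics import radial_profile
from spisort.simdata import (
    DetectorGeometry,
    ParticleModel,
    SimConfig,
    generate_dataset,
    ground_truth_intensity,
    largest_remainder_counts,
    make_icosahedron_density,
    random_quaternion,
    render_multi_hit,
    render_nonhit,
    render_single_hit,
    sphere_form_factor,
)


def _independent_icosahedron_normals():
    """Face normals derived from the 12-vertex construction via a convex
    hull — an independent route to the face-plane geometry."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            verts += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    verts = np.asarray(verts)
    hull = ConvexHull(verts)
    normals = []
    for simplex in hull.simplices:
        c = verts[simplex].mean(axis=0)
        normals.append(c / np.linalg.norm(c))
    return np.asarray(normals)


class TestIcosahedronDensity:
    def test_centred_particle_has_inversion_symmetry(self):
        model = ParticleModel(core_offset=(0.0, 0.0, 0.0))
        d = make_icosahedron_density(model).values
        assert np.allclose(d, point_reflect(d), atol=1e-12)

    def test_voxel_count_matches_monte_carlo_volume(self):
        # solid icosahedron (capsid == core density), hard edges
        model = ParticleModel(grid_size=64, inradius=10.0, edge_softness=0.0,
                              capsid_density=1.0, core_density=1.0)
        voxels = int(np.sum(make_icosahedron_density(model).values > 0.5))
        normals = _independent_icosahedron_normals()
        rng = np.random.default_rng(0)
        pts = rng.uniform(-14.0, 14.0, (2_000_000, 3))
        # unit face normals: the solid {max(p . n) <= r} has inradius r
        inside = (pts @ normals.T).max(axis=1) <= 10.0
        mc_volume = inside.mean() * 28.0 ** 3
        assert voxels == pytest.approx(mc_volume, rel=0.03)

    def test_zero_densities_give_zero_map(self):
        model = ParticleModel(capsid_density=0.0, core_density=0.0)
        assert not make_icosahedron_density(model).values.any()

    def test_oversized_particle_rejected(self):
        with pytest.raises(ValueError, match="exceeds grid"):
            ParticleModel(grid_size=16, inradius=10.0)

    def test_offset_core_breaks_inversion_symmetry(self):
        model = ParticleModel(core_offset=(0.0, 0.0, 4.0))
        d = make_icosahedron_density(model).values
        assert not np.allclose(d, point_reflect(d), atol=1e-6)


class TestGroundTruthIntensity:
    def test_friedel_symmetry_exact(self, ground_truth_volume):
        i = ground_truth_volume.intensities
        assert np.max(np.abs(i - point_reflect(i))) <= 1e-6 * i.max()

    def test_intensity_scales_quadratically_with_density(self):
        model = ParticleModel(grid_size=16, inradius=5.0, core_radius=2.0,
                              edge_softness=0.5)
        d = make_icosahedron_density(model)
        v1 = ground_truth_intensity(d, 2.0).intensities
        v2 = ground_truth_intensity(
            DensityMap(values=3.0 * d.values, voxel_size=d.voxel_size), 2.0
        ).intensities
        assert np.allclose(v2, 9.0 * v1, rtol=1e-10, atol=1e-6 * v1.max())

    def test_low_oversampling_rejected(self, particle_model):
        d = make_icosahedron_density(particle_model)
        with pytest.raises(ValueError, match="oversampling"):
            ground_truth_intensity(d, 1.5)

    def test_sphere_radial_average_matches_form_factor(self):
        # antialiased ball: one-voxel linear edge ramp
        n, radius = 48, 10.0
        ax = np.arange(n) - n // 2
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        r = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
        ball = np.clip(radius + 0.5 - r, 0.0, 1.0)
        vol = ground_truth_intensity(DensityMap(values=ball, voxel_size=1.0), 3.0)
        prof = radial_profile(vol, n_bins=60)
        norm = prof.values / prof.values[0]
        ana = sphere_form_factor(prof.q_centers, radius)
        # relative comparison away from the minima shoulders, where the
        # binned average of a digitized sphere cannot follow the zeros
        third_min = 10.904 / radius
        sel = (prof.q_centers <= third_min) & (ana >= 1e-2)
        rel = np.abs(norm[sel] - ana[sel]) / ana[sel]
        assert np.max(rel) < 0.06


class TestSphereFormFactor:
    def test_zero_q_limit_is_one(self):
        assert sphere_form_factor(0.0, 5.0) == pytest.approx(1.0)

    def test_value_at_qr_pi(self):
        # x = pi: [3 (0 - pi (-1)) / pi^3]^2 = (3 / pi^2)^2
        expected = (3.0 / math.pi ** 2) ** 2
        assert sphere_form_factor(math.pi / 7.0, 7.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.0923, abs=5e-4)

    def test_non_negative_everywhere(self):
        q = np.linspace(0.0, 50.0, 2001)
        assert np.all(sphere_form_factor(q, 3.0) >= 0.0)


class TestRenderSingleHit:
    def test_zero_photons_zero_noise_gives_zero_frame(self, ground_truth_volume):
        geom = DetectorGeometry(read_noise_adu=0.0)
        fr = render_single_hit(ground_truth_volume, (1, 0, 0, 0), geom, 0.0,
                               np.random.default_rng(0))
        assert not fr.values.any()

    def test_identity_orientation_equals_central_slab(self, ground_truth_volume):
        geom = DetectorGeometry(beam_center=(32.0, 32.0), read_noise_adu=0.0)
        fr = render_single_hit(ground_truth_volume, (1, 0, 0, 0), geom, None,
                               noiseless=True)
        c = ground_truth_volume.shape[0] // 2
        slab = ground_truth_volume.intensities[c - 32:c + 32, c - 32:c + 32, c]
        assert np.allclose(fr.values, slab, rtol=1e-10)

    def test_same_seed_gives_identical_frame(self, ground_truth_volume, geometry):
        frames = [render_single_hit(ground_truth_volume, (1, 0, 0, 0), geometry,
                                    1000.0, np.random.default_rng(11)).values
                  for _ in range(2)]
        assert np.array_equal(frames[0], frames[1])

    def test_noiseless_frame_friedel_symmetric(self, ground_truth_volume):
        geom = DetectorGeometry(beam_center=(32.0, 32.0))
        q = random_quaternion(np.random.default_rng(4))
        fr = render_single_hit(ground_truth_volume, q, geom, None,
                               noiseless=True).values
        mate = point_reflect(fr)
        # interpolation tolerance: symmetric up to a few percent of peak
        assert np.max(np.abs(fr - mate)) < 0.03 * fr.max()

    def test_bad_pixels_get_sentinel(self, ground_truth_volume):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:12, 20:30] = True
        geom = DetectorGeometry(mask=mask)
        fr = render_single_hit(ground_truth_volume, (1, 0, 0, 0), geom, 100.0,
                               np.random.default_rng(0))
        assert np.all(fr.values[mask] < 0)
        assert fr.mask[10, 25]


class TestRenderMultiHit:
    def test_zero_displacement_identical_orientations_quadruple(self, ground_truth_volume):
        geom = DetectorGeometry(beam_center=(32.0, 32.0))
        q = (1.0, 0.0, 0.0, 0.0)
        single = render_single_hit(ground_truth_volume, q, geom, None,
                                   noiseless=True).values
        double = render_multi_hit(ground_truth_volume, (q, q), (0, 0, 0), geom,
                                  None, noiseless=True).values
        assert np.allclose(double, 4.0 * single, rtol=1e-8, atol=1e-6 * single.max())

    def test_fringes_show_autocorrelation_side_peaks(self, ground_truth_volume):
        geom = DetectorGeometry(beam_center=(32.0, 32.0))
        q = (1.0, 0.0, 0.0, 0.0)
        # displacement large enough that the autocorrelation side peaks
        # clear the central (particle-autocorrelation) envelope
        d_vox = 30.0  # along detector row axis
        frame = render_multi_hit(ground_truth_volume, (q, q), (d_vox, 0, 0),
                                 geom, None, noiseless=True).values
        ac = np.abs(np.fft.fftshift(np.fft.ifft2(frame)))
        c = 32
        expected = d_vox * 64 / ground_truth_volume.shape[0]  # pixels
        # blank the central envelope, keep the side-peak region
        rows = np.abs(np.arange(64) - c)
        ac[rows < expected - 3, :] = 0.0
        peak = np.unravel_index(np.argmax(ac), ac.shape)
        assert abs(abs(peak[0] - c) - expected) <= 1.0
        assert peak[1] == c

    def test_zero_second_particle_reduces_to_single_hit(self, ground_truth_volume):
        from spisort.containers import IntensityVolume

        geom = DetectorGeometry(beam_center=(32.0, 32.0))
        empty = IntensityVolume(
            intensities=np.zeros(ground_truth_volume.shape),
            q_calibration=ground_truth_volume.q_calibration,
            amplitudes=np.zeros(ground_truth_volume.shape, dtype=complex))
        # identity orientation + integer beam centre sample exact voxels,
        # where interpolating amplitudes and intensities agree exactly
        q = (1.0, 0.0, 0.0, 0.0)
        multi = render_multi_hit(ground_truth_volume, (q, q), (5, 3, 0), geom,
                                 None, volume2=empty, noiseless=True).values
        single = render_single_hit(ground_truth_volume, q, geom, None,
                                   noiseless=True).values
        assert np.allclose(multi, single, rtol=1e-8, atol=1e-9 * single.max())


class TestRenderNonhit:
    def test_zero_radius_zero_rate_gives_zero(self, geometry):
        fr = render_nonhit(DetectorGeometry(read_noise_adu=0.0), 0.0, 0.0,
                           np.random.default_rng(0))
        assert not fr.values.any()

    def test_background_poisson_mean(self):
        geom = DetectorGeometry(n_pixels=16, beam_center=(7.5, 7.5),
                                read_noise_adu=0.0, gain=1.0)
        rng = np.random.default_rng(5)
        rate = 0.4
        n = 400
        acc = np.zeros((16, 16))
        for _ in range(n):
            acc += render_nonhit(geom, 0.0, rate, rng).values
        mean = acc.mean() / n
        se = math.sqrt(rate / (n * 256))
        assert abs(mean - rate) < 3.0 * se

    def test_droplet_minima_at_sphere_roots(self, geometry):
        radius_nm = 30.0
        fr = render_nonhit(geometry, radius_nm, 0.0, noiseless=True,
                           droplet_photons=1e6)
        curve = radial_profile(fr.values, geometry, n_bins=48)
        v, q = curve.values, curve.q_centers
        minima = [q[i] * radius_nm for i in range(1, len(v) - 1)
                  if v[i] < v[i - 1] and v[i] < v[i + 1]]
        # roots of tan x = x: 4.493, 7.725
        assert minima[0] == pytest.approx(4.493, rel=0.03)
        assert minima[1] == pytest.approx(7.725, rel=0.03)


class TestPoissonEnsemble:
    def test_ensemble_mean_matches_noiseless_intensity(self, ground_truth_volume):
        geom = DetectorGeometry(n_pixels=16, beam_center=(7.5, 7.5),
                                gain=1.0, read_noise_adu=0.0)
        q = random_quaternion(np.random.default_rng(9))
        lam = render_single_hit(ground_truth_volume, q, geom, 500.0,
                                noiseless=True).values
        rng = np.random.default_rng(10)
        n = 1200
        acc = np.zeros_like(lam)
        for _ in range(n):
            acc += render_single_hit(ground_truth_volume, q, geom, 500.0, rng).values
        mean = acc / n
        sel = lam > 0.05
        chi2 = np.mean((mean[sel] - lam[sel]) ** 2 * n / lam[sel])
        assert 0.8 < chi2 < 1.2


class TestAveragedProfile:
    def test_many_single_hits_approach_spherical_average(self, ground_truth_volume,
                                                         geometry):
        rng = np.random.default_rng(3)
        acc = np.zeros((64, 64))
        n = 1000
        for _ in range(n):
            acc += render_single_hit(ground_truth_volume, random_quaternion(rng),
                                     geometry, None, noiseless=True).values
        acc /= n
        fine = radial_profile(ground_truth_volume, n_bins=96)
        good = np.isfinite(fine.values)
        expect = np.interp(geometry.q_radii(), fine.q_centers[good],
                           fine.values[good])
        p_meas = radial_profile(acc, geometry, n_bins=16)
        p_exp = radial_profile(expect, geometry, n_bins=16)
        sel = p_meas.q_centers <= 32 * geometry.pixel_q_step
        rel = np.abs(p_meas.values[sel] - p_exp.values[sel]) / p_exp.values[sel]
        assert np.nanmedian(rel) < 0.03
        assert np.nanmax(rel) < 0.075


class TestDatasetAssembly:
    def test_largest_remainder_hand_example(self):
        counts = largest_remainder_counts((0.395, 0.35, 0.255), 200)
        assert counts.tolist() == [79, 70, 51]

    @pytest.mark.parametrize("n", [1, 7, 33, 200])
    def test_largest_remainder_properties(self, n):
        fr = (0.21, 0.485, 0.305)
        counts = largest_remainder_counts(fr, n)
        assert counts.sum() == n
        exact = np.array(fr) * n
        assert np.all(np.abs(counts - exact) < 1.0)

    def test_pure_single_fractions(self):
        cfg = SimConfig(n_patterns=10, fraction_single=1.0, fraction_multi=0.0,
                        fraction_nonhit=0.0, rng_seed=1, train_size=0)
        _, truth, _ = generate_dataset(cfg)
        assert all(l == "single" for l in truth.labels)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(fraction_single=0.5, fraction_multi=0.5,
                      fraction_nonhit=0.5)

    def test_generation_deterministic(self):
        cfg = SimConfig(n_patterns=14, rng_seed=21, train_size=6,
                        train_singles=3)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        assert np.array_equal(a[0].frames, b[0].frames)
        assert np.array_equal(a[1].labels, b[1].labels)
        assert np.array_equal(a[1].orientations, b[1].orientations)

    def test_training_subset_composition(self):
        cfg = SimConfig(n_patterns=500, rng_seed=2, train_size=200,
                        train_singles=79)
        _, truth, _ = generate_dataset(cfg)
        sub = truth.labels[truth.train_mask]
        assert truth.train_mask.sum() == 200
        assert np.sum(sub == "single") == 79
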