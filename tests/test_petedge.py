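"""Radial gradient segmenter: ray sampling, edge placement, regularization,
rasterization, and end-to-end phantom recovery."""

import numpy as np
import pytest
from scipy.special import erf

from segmargin import (
    BinaryMask,
    NoEdgeError,
    PetEdgeParams,
    PetParams,
    RadialEdgeModel,
    ScalarImage,
    dice,
    edge_along_ray,
    icosphere_directions,
    mask_volume_ml,
    petedge_segment,
    radii_to_mask,
    regularize_radii,
    sample_ray,
    simulate_pet,
)
from conftest import ball, lattice_ball_count


def blurred_ball_image(shape, center, radius, sigma, contrast=10.0, bg=1.0):
    """Phantom via the package's own convolution-based generator."""
    truth = ball(shape, center, radius)
    fwhm = sigma * 2.0 * np.sqrt(2.0 * np.log(2.0))
    return truth, simulate_pet(
        truth,
        PetParams(background_suv=bg, tumor_suv=contrast, psf_fwhm_mm=fwhm,
                  noise_sd_fraction=0.0),
    )


class TestSampleRay:
    def test_constant_image_gives_constant_profile(self):
        img = ScalarImage(np.full((10, 10, 10), 3.5), (1, 1, 1))
        prof, outside = sample_ray(img, (4.5, 4.5, 4.5), (1, 0, 0), 0.5, 4.0)
        assert np.allclose(prof, 3.5)
        assert not outside[: len(prof) - 1].any()

    def test_axis_aligned_ray_reproduces_voxel_values(self):
        data = np.zeros((10, 4, 4))
        data[:, 1, 2] = np.arange(10, dtype=float)
        img = ScalarImage(data, (1, 1, 1))
        prof, _ = sample_ray(img, (0.0, 1.0, 2.0), (1, 0, 0), 1.0, 9.0)
        assert np.allclose(prof, np.arange(10.0))

    def test_seed_outside_image_raises(self):
        img = ScalarImage(np.zeros((5, 5, 5)), (1, 1, 1))
        with pytest.raises(ValueError, match="outside"):
            sample_ray(img, (10.0, 2.0, 2.0), (1, 0, 0), 0.5, 3.0)

    def test_analytic_blurred_sphere_profile_matches_closed_form(self):
        """Rays through an image built from the closed-form blurred-sphere
        field reproduce the 1D closed form at the sample points."""
        R, sigma, bg, peak = 10.0, 1.5, 1.0, 10.0
        s2 = sigma * np.sqrt(2.0)

        def ball_blur(r):
            r = np.maximum(np.asarray(r, float), 1e-9)
            core = 0.5 * (erf((R - r) / s2) + erf((R + r) / s2))
            tail = (sigma / (r * np.sqrt(2.0 * np.pi))) * (
                np.exp(-((r - R) ** 2) / (2 * sigma**2))
                - np.exp(-((r + R) ** 2) / (2 * sigma**2))
            )
            return bg + (peak - bg) * (core - tail)

        shape = (41, 41, 41)
        c = np.array([20.0, 20.0, 20.0])
        ax = np.arange(41.0)
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        rr = np.sqrt((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2)
        img = ScalarImage(ball_blur(rr), (1, 1, 1))

        # axis-aligned ray at voxel-center steps: exact reproduction
        prof, _ = sample_ray(img, tuple(c), (1, 0, 0), 1.0, 14.0)
        assert np.allclose(prof, ball_blur(np.arange(len(prof))), atol=1e-9)

        # oblique ray: matches to trilinear-interpolation tolerance
        d = np.array([1.0, 1.0, 0.5])
        prof, _ = sample_ray(img, tuple(c), tuple(d), 0.25, 14.0)
        r = np.arange(len(prof)) * 0.25
        assert np.allclose(prof, ball_blur(r), atol=0.3)


class TestEdgeAlongRay:
    def test_step_profile_edge_at_transition_midpoint(self):
        r = edge_along_ray(np.array([10.0, 10, 10, 1, 1, 1]), 1.0)
        assert r == pytest.approx(2.5)

    def test_constant_profile_has_no_edge(self):
        assert edge_along_ray(np.full(10, 4.2), 1.0) is None

    def test_monotone_increasing_profile_has_no_edge(self):
        assert edge_along_ray(np.linspace(1, 10, 12), 1.0) is None

    def test_erf_profile_recovers_inflection(self):
        """For a blurred ideal edge the recovered radius is the inflection
        point (= true edge location) to sub-step accuracy."""
        step, sigma, r_true = 0.5, 2.0, 7.3
        r = np.arange(0, 15, step)
        profile = 0.5 * (1.0 - erf((r - r_true) / (sigma * np.sqrt(2.0))))
        assert edge_along_ray(profile, step) == pytest.approx(r_true, abs=0.05)

    def test_intensity_scale_invariance(self):
        p = np.array([10.0, 10, 9, 4, 1, 1, 1])
        assert edge_along_ray(p, 1.0) == edge_along_ray(p * 137.0, 1.0)

    def test_too_short_profile_raises(self):
        with pytest.raises(ValueError):
            edge_along_ray(np.array([1.0, 2.0]), 1.0)


def make_model(radii, n=42, seed_mm=(0.0, 0.0, 0.0)):
    dirs, nbrs = icosphere_directions(n)
    return RadialEdgeModel(seed_mm=seed_mm, directions=dirs,
                           radii_mm=np.asarray(radii, float), neighbours=nbrs)


class TestRegularize:
    def test_uniform_radii_fixed_point(self):
        model = make_model(np.full(42, 7.0))
        out = regularize_radii(model)
        assert np.allclose(out.radii_mm, 7.0)

    def test_single_outlier_replaced_by_neighbour_median(self):
        radii = np.full(42, 6.0)
        radii[10] = 18.0  # 3x the neighbour median
        out = regularize_radii(make_model(radii))
        assert out.radii_mm[10] == pytest.approx(6.0)

    def test_missing_radii_imputed_on_sphere(self, rng):
        radii = np.full(162, 9.0)
        missing = rng.choice(162, size=8, replace=False)
        radii[missing] = np.nan
        out = regularize_radii(make_model(radii, n=162))
        assert np.allclose(out.radii_mm, 9.0, atol=1.0)

    def test_all_missing_raises(self):
        with pytest.raises(NoEdgeError):
            regularize_radii(make_model(np.full(42, np.nan)))


class TestRadiiToMask:
    def test_constant_radius_rasterizes_to_ball(self):
        R = 6.0
        grid = BinaryMask(np.zeros((21, 21, 21), bool), (1, 1, 1))
        model = make_model(np.full(162, R), n=162, seed_mm=(10.0, 10.0, 10.0))
        mask = radii_to_mask(model, grid)
        expected = lattice_ball_count(R)
        # allow a band of surface voxels for direction-interpolation error
        assert abs(mask.count() - expected) <= 0.1 * expected

    def test_tiny_radius_keeps_seed_voxel(self):
        grid = BinaryMask(np.zeros((9, 9, 9), bool), (1, 1, 1))
        model = make_model(np.full(42, 0.2), seed_mm=(4.0, 4.0, 4.0))
        mask = radii_to_mask(model, grid)
        assert mask.data[4, 4, 4]
        assert mask.count() >= 1

    def test_ellipsoidal_field_extents(self):
        from segmargin import max_extents

        dirs, nbrs = icosphere_directions(642)
        axes = np.array([10.0, 7.0, 5.0])
        radii = 1.0 / np.sqrt(np.sum((dirs / axes) ** 2, axis=1))
        model = RadialEdgeModel((15.0, 15.0, 15.0), dirs, radii, nbrs)
        grid = BinaryMask(np.zeros((31, 31, 31), bool), (1, 1, 1))
        mask = radii_to_mask(model, grid)
        ext = tuple(max_extents(mask))
        for e, a in zip(ext, axes):
            assert abs(e - 2 * a) <= 2.0  # within one voxel per side

    def test_unregularized_model_rejected(self):
        radii = np.full(42, 5.0)
        radii[3] = np.nan
        grid = BinaryMask(np.zeros((15, 15, 15), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            radii_to_mask(make_model(radii, seed_mm=(7.0, 7.0, 7.0)), grid)


class TestPetEdgeSegment:
    def test_sphere_phantom_recovers_radius(self):
        """8 mm ball, 10:1 contrast, 4.1 mm FWHM PSF, no noise: the
        recovered equivalent-sphere radius is within one voxel."""
        shape = (52, 52, 52)
        c = (25.5, 25.5, 25.5)
        truth = ball(shape, c, 8.0)
        img = simulate_pet(truth, PetParams(background_suv=1.0, tumor_suv=10.0,
                                            psf_fwhm_mm=4.1, noise_sd_fraction=0.0))
        seg = petedge_segment(img, c)
        r_eq = (3.0 * seg.count() / (4.0 * np.pi)) ** (1.0 / 3.0)
        assert abs(r_eq - 8.0) <= 1.0

    def test_displaced_seed_still_recovers(self):
        shape = (52, 52, 52)
        c = np.array([25.5, 25.5, 25.5])
        truth = ball(shape, tuple(c), 8.0)
        img = simulate_pet(truth, PetParams(noise_sd_fraction=0.0))
        seg = petedge_segment(img, tuple(c + [2.0, 0.0, 0.0]))
        assert dice(seg, truth) >= 0.9

    def test_deterministic(self):
        shape = (40, 40, 40)
        c = (19.5, 19.5, 19.5)
        truth = ball(shape, c, 7.0)
        img = simulate_pet(truth, PetParams(noise_sd_fraction=0.0))
        a = petedge_segment(img, c)
        b = petedge_segment(img, c)
        assert np.array_equal(a.data, b.data)

    def test_intensity_scale_invariance(self):
        shape = (40, 40, 40)
        c = (19.5, 19.5, 19.5)
        truth = ball(shape, c, 7.0)
        img = simulate_pet(truth, PetParams(noise_sd_fraction=0.0))
        scaled = ScalarImage(img.data * 11.7, img.spacing, img.origin)
        assert np.array_equal(
            petedge_segment(img, c).data, petedge_segment(scaled, c).data
        )

    def test_zero_contrast_raises_no_edge(self):
        img = ScalarImage(np.full((20, 20, 20), 2.0), (1, 1, 1))
        with pytest.raises(NoEdgeError):
            petedge_segment(img, (9.5, 9.5, 9.5))

    def test_output_connected_and_contains_seed(self):
        from scipy import ndimage

        shape = (44, 44, 44)
        c = (21.5, 21.5, 21.5)
        truth = ball(shape, c, 9.0)
        rng = np.random.default_rng(3)
        img = simulate_pet(truth, PetParams(noise_sd_fraction=0.1), rng)
        seg = petedge_segment(img, c)
        _, n_comp = ndimage.label(seg.data, structure=np.ones((3, 3, 3)))
        assert n_comp == 1
        assert seg.data[21, 21, 21] or seg.data[22, 22, 22]
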