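"""Overlap and surface-distance metrics against counting and O(n^2) oracles."""

import numpy as np
import pytest

from segmargin import (
    BinaryMask,
    dice,
    directed_surface_distances,
    hausdorff_mm,
    jaccard,
    mda_mm,
    missed_volume,
    similarity_report,
    surface_voxels,
)
from conftest import (
    box,
    brute_hausdorff,
    brute_mda,
    random_mask,
)


def single_voxel(pos, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)):
    data = np.zeros(shape, bool)
    data[pos] = True
    return BinaryMask(data, spacing)


class TestOverlap:
    def test_identical_masks_are_perfect(self, rng):
        m = random_mask(rng)
        assert dice(m, m) == 1.0
        assert jaccard(m, m) == 1.0

    def test_disjoint_masks_are_zero(self):
        a = box((10, 10, 10), (0, 0, 0), (3, 3, 3))
        b = box((10, 10, 10), (6, 6, 6), (9, 9, 9))
        assert dice(a, b) == 0.0
        assert jaccard(a, b) == 0.0

    def test_half_overlapping_cubes(self):
        a = box((20, 10, 10), (0, 0, 0), (10, 10, 10))
        b = box((20, 10, 10), (5, 0, 0), (15, 10, 10))
        assert dice(a, b) == pytest.approx(0.5)
        assert jaccard(a, b) == pytest.approx(1.0 / 3.0)

    def test_both_empty_raises(self):
        e = BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            dice(e, e)
        with pytest.raises(ValueError):
            jaccard(e, e)

    def test_jaccard_dice_identity_and_symmetry(self, rng):
        for _ in range(30):
            a, b = random_mask(rng), random_mask(rng)
            d, j = dice(a, b), jaccard(a, b)
            assert j == pytest.approx(d / (2.0 - d), abs=1e-12)
            assert j <= d + 1e-15
            assert dice(b, a) == d
            assert jaccard(b, a) == j


class TestSurface:
    def test_single_voxel_is_its_own_surface(self):
        m = single_voxel((3, 3, 3))
        assert np.array_equal(surface_voxels(m).data, m.data)

    def test_cube_surface_counts(self):
        assert surface_voxels(box((5, 5, 5), (1, 1, 1), (4, 4, 4))).count() == 26
        assert surface_voxels(box((12, 12, 12), (1, 1, 1), (11, 11, 11))).count() == 488

    def test_lattice_boundary_voxels_are_surface(self):
        m = box((4, 4, 4), (0, 0, 0), (4, 4, 4))  # fills the lattice
        # interior 2x2x2 core is not surface
        assert surface_voxels(m).count() == 64 - 8

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            surface_voxels(BinaryMask(np.zeros((3, 3, 3), bool), (1, 1, 1)))


class TestDistances:
    def test_identical_surfaces_all_zero(self, rng):
        m = random_mask(rng)
        assert directed_surface_distances(m, m).max() == 0.0
        assert hausdorff_mm(m, m) == 0.0
        assert mda_mm(m, m) == 0.0

    def test_single_voxels_axis_separation(self):
        a = single_voxel((1, 4, 4))
        b = single_voxel((4, 4, 4))
        assert directed_surface_distances(a, b).tolist() == [3.0]
        assert hausdorff_mm(a, b) == pytest.approx(3.0)
        assert mda_mm(a, b) == pytest.approx(3.0)

    def test_anisotropic_spacing_scales_distance(self):
        a = single_voxel((1, 4, 4), spacing=(2, 1, 1))
        b = single_voxel((4, 4, 4), spacing=(2, 1, 1))
        assert directed_surface_distances(a, b).tolist() == [6.0]

    def test_oracle_equivalence_random_pairs(self, rng):
        """EDT path equals exhaustive pairwise scanning on small grids."""
        for _ in range(25):
            a = random_mask(rng, shape=(12, 12, 12), p=0.25)
            b = random_mask(rng, shape=(12, 12, 12), p=0.25)
            assert hausdorff_mm(a, b) == pytest.approx(brute_hausdorff(a, b), abs=1e-9)
            assert mda_mm(a, b) == pytest.approx(brute_mda(a, b), abs=1e-9)

    def test_oracle_equivalence_anisotropic(self, rng):
        sp = (0.7, 0.9, 3.0)
        for _ in range(10):
            a = random_mask(rng, shape=(10, 10, 10), spacing=sp, p=0.25)
            b = random_mask(rng, shape=(10, 10, 10), spacing=sp, p=0.25)
            assert hausdorff_mm(a, b) == pytest.approx(brute_hausdorff(a, b), abs=1e-9)
            assert mda_mm(a, b) == pytest.approx(brute_mda(a, b), abs=1e-9)

    def test_spacing_scaling_covariance(self, rng):
        a0 = random_mask(rng, shape=(10, 10, 10))
        b0 = random_mask(rng, shape=(10, 10, 10))
        s = 2.5
        a1 = BinaryMask(a0.data, tuple(s * x for x in a0.spacing))
        b1 = BinaryMask(b0.data, tuple(s * x for x in b0.spacing))
        assert hausdorff_mm(a1, b1) == pytest.approx(s * hausdorff_mm(a0, b0))
        assert mda_mm(a1, b1) == pytest.approx(s * mda_mm(a0, b0))
        assert dice(a1, b1) == dice(a0, b0)
        assert jaccard(a1, b1) == jaccard(a0, b0)


class TestMissedVolume:
    def test_full_coverage_misses_nothing(self, rng):
        truth = box((12, 12, 12), (3, 3, 3), (8, 8, 8))
        candidate = box((12, 12, 12), (2, 2, 2), (9, 9, 9))
        assert missed_volume(truth, candidate) == (0.0, 0.0)

    def test_disjoint_candidate_misses_everything(self):
        truth = box((20, 10, 10), (0, 0, 0), (10, 10, 10))
        cand = box((20, 10, 10), (11, 0, 0), (19, 9, 9))
        ml, pct = missed_volume(truth, cand)
        assert ml == pytest.approx(1.0)
        assert pct == pytest.approx(100.0)

    def test_half_covered_cube(self):
        truth = box((20, 10, 10), (0, 0, 0), (10, 10, 10))
        cand = box((20, 10, 10), (5, 0, 0), (15, 10, 10))
        ml, pct = missed_volume(truth, cand)
        assert ml == pytest.approx(0.5)
        assert pct == pytest.approx(50.0)

    def test_empty_truth_raises(self):
        e = BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        c = box((4, 4, 4), (0, 0, 0), (2, 2, 2))
        with pytest.raises(ValueError):
            missed_volume(e, c)


class TestSimilarityReport:
    def test_perfect_candidate(self, rng):
        m = random_mask(rng)
        rep = similarity_report(m, m)
        assert (rep.dice, rep.jaccard, rep.hd_mm, rep.mda_mm) == (1.0, 1.0, 0.0, 0.0)
        assert rep.missed_volume_ml == 0.0

    def test_half_overlap_report_matches_hand_computation(self):
        truth = box((20, 10, 10), (0, 0, 0), (10, 10, 10))
        cand = box((20, 10, 10), (5, 0, 0), (15, 10, 10))
        rep = similarity_report(truth, cand)
        assert rep.dice == pytest.approx(0.5)
        assert rep.jaccard == pytest.approx(1.0 / 3.0)
        assert rep.missed_percent == pytest.approx(50.0)
        assert rep.truth_volume_ml == pytest.approx(1.0)
        assert rep.candidate_volume_ml == pytest.approx(1.0)

    def test_report_invariants_on_random_pairs(self, rng):
        for _ in range(20):
            a, b = random_mask(rng), random_mask(rng)
            rep = similarity_report(a, b)
            assert rep.jaccard <= rep.dice + 1e-15
            assert rep.mda_mm <= rep.hd_mm + 1e-12
            assert 0 <= rep.missed_percent <= 100
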