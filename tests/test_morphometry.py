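import dataclasses

import numpy as np
import pytest

from granuleseg.io_config import GrayImage
from granuleseg.morphometry import (
    compare_groups,
    distance_profile,
    granule_density,
    match_cores,
    measure_granule,
    measure_scene,
    membrane_distance,
    summarize_population,
)
from granuleseg.synthetic import SceneSpec, generate_scene
from tests.conftest import render_capsule, render_disc


def _scene_image(mask, value=37, bg=120, pixel_size_nm=10.0):
    px = np.where(mask, value, bg).astype(np.uint8)
    return GrayImage(px, pixel_size_nm)


class TestMeasureGranule:
    def test_disc_equiv_radius_analytic(self):
        """An anti-aliased 10 px disc at 10 nm/px measures 100 +- 2 nm."""
        _, mask = render_disc(10)
        rec = measure_granule(mask.astype(np.int32), 1, _scene_image(mask))
        assert rec.equiv_radius_nm == pytest.approx(100.0, abs=2.0)

    def test_disc_round_coefficient_near_one(self):
        _, mask = render_disc(10)
        rec = measure_granule(mask.astype(np.int32), 1, _scene_image(mask))
        assert 0.95 <= rec.round_coefficient <= 1.05

    def test_mean_gray_exact_on_uniform_instance(self):
        _, mask = render_disc(8)
        rec = measure_granule(mask.astype(np.int32), 1, _scene_image(mask, value=37))
        assert rec.mean_gray == 37.0

    def test_centroid_matches_disc_center(self):
        _, mask = render_disc(10, center=(30.0, 26.0))
        rec = measure_granule(mask.astype(np.int32), 1, _scene_image(mask))
        assert rec.centroid[0] == pytest.approx(30.0, abs=0.2)
        assert rec.centroid[1] == pytest.approx(26.0, abs=0.2)

    def test_capsule_less_round_than_equal_area_disc(self):
        """A 2:1 rod scores below the disc and near its analytic ratio."""
        _, disc = render_disc(10)
        area = disc.sum()
        capsule = render_capsule(2.0, area)
        rec_d = measure_granule(disc.astype(np.int32), 1, _scene_image(disc))
        rec_c = measure_granule(capsule.astype(np.int32), 1, _scene_image(capsule))
        assert rec_c.round_coefficient < rec_d.round_coefficient
        # analytic capsule: area = pi rho^2 + 4 ell rho, perimeter = 2 pi rho + 4 ell
        rho = np.sqrt(area / (np.pi + 4.0))  # aspect 2 -> ell = rho
        perim = 2 * np.pi * rho + 4 * rho
        analytic = 4 * np.pi * area / perim**2
        assert rec_c.round_coefficient == pytest.approx(analytic, rel=0.05)

    @pytest.mark.parametrize("radius", [5, 7, 10, 16])
    def test_disc_beats_capsule_across_radii(self, radius):
        _, disc = render_disc(radius)
        capsule = render_capsule(2.5, disc.sum())
        rc_d = measure_granule(disc.astype(np.int32), 1, _scene_image(disc)).round_coefficient
        rc_c = measure_granule(capsule.astype(np.int32), 1, _scene_image(capsule)).round_coefficient
        assert rc_d >= rc_c

    def test_missing_id_raises(self):
        _, mask = render_disc(5)
        with pytest.raises(KeyError):
            measure_granule(mask.astype(np.int32), 7, _scene_image(mask))

    def test_radius_recovery_on_noise_free_scene(self):
        """Measured radii match the generator's ground truth within 2%+0.5 px."""
        spec = SceneSpec(
            noise_sigma=0.0, illumination_gradient_amplitude=0.0,
            nucleus_present=False, target_density_per_um2=1.03, seed=17,
        )
        truth = generate_scene(spec)
        img = truth.image
        checked = 0
        for k, g in enumerate(truth.granule_params, start=1):
            if g["radius_px"] < 5:
                continue
            # skip granules that overlap a neighbour (their pixel area is shared)
            area_px = (truth.granule_instances == k).sum()
            if abs(area_px - np.pi * g["radius_px"] ** 2) > 0.1 * np.pi * g["radius_px"] ** 2:
                continue
            rec = measure_granule(truth.granule_instances, k, img)
            tol = 0.02 * g["radius_nm"] + 0.5 * spec.pixel_size_nm
            assert abs(rec.equiv_radius_nm - g["radius_nm"]) < tol
            checked += 1
        assert checked > 0


class TestCores:
    def test_core_matched_and_measured(self):
        spec = SceneSpec(
            noise_sigma=0.0, illumination_gradient_amplitude=0.0,
            nucleus_present=False, target_density_per_um2=1.0,
            rod_core_fraction=0.0, seed=23,
        )
        truth = generate_scene(spec)
        assert truth.n_granules > 0
        records = measure_scene(truth.granule_instances, truth.image,
                                core_map=truth.core_instances)
        by_id = {r.id: r for r in records}
        for k, g in enumerate(truth.granule_params, start=1):
            if g["radius_px"] * spec.core_to_granule_radius_ratio < 3:
                continue
            rec = by_id[k]
            assert rec.core_radius_nm is not None
            assert rec.core_radius_nm == pytest.approx(
                g["core_radius_nm"], rel=0.1, abs=spec.pixel_size_nm
            )

    def test_match_cores_maximal_overlap(self):
        imap = np.zeros((32, 32), dtype=np.int32)
        imap[:, :16] = 1
        imap[:, 16:] = 2
        cores = np.zeros_like(imap)
        cores[10:20, 10:20] = 1  # 6 columns in granule 1, 4 in granule 2
        assert match_cores(imap, cores) == {1: 1}


class TestMembraneDistance:
    def test_boundary_point_on_polyline_gives_zero(self):
        _, mask = render_disc(10, center=(32.0, 32.0))
        rec = measure_granule(mask.astype(np.int32), 1, _scene_image(mask))
        membrane = np.array([rec.boundary[3], rec.boundary[10]])
        assert membrane_distance(rec, np.vstack([membrane, rec.boundary[3]]), 10.0) == pytest.approx(0.0, abs=1e-9)

    def test_disc_to_straight_line_analytic(self):
        """Disc r=10 px centered 30 px from a line at 10 nm/px -> 200 nm."""
        _, mask = render_disc(10, shape=(64, 64), center=(32.0, 40.0))
        rec = measure_granule(mask.astype(np.int32), 1, _scene_image(mask))
        membrane = np.array([[0.0, 10.0], [63.0, 10.0]])  # vertical line col=10
        d = membrane_distance(rec, membrane, 10.0)
        assert d == pytest.approx(200.0, abs=5.0)  # within half a pixel

    def test_invariant_under_rigid_rotation(self):
        _, mask = render_disc(10, center=(32.0, 40.0))
        rec = measure_granule(mask.astype(np.int32), 1, _scene_image(mask))
        membrane = np.array([[0.0, 10.0], [63.0, 10.0]])
        d0 = membrane_distance(rec, membrane, 10.0)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        d1 = membrane_distance(rec.boundary @ rot.T, membrane @ rot.T, 10.0)
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_empty_polyline_rejected(self):
        _, mask = render_disc(5)
        rec = measure_granule(mask.astype(np.int32), 1, _scene_image(mask))
        with pytest.raises(ValueError):
            membrane_distance(rec, np.zeros((0, 2)), 10.0)


class TestDensity:
    def test_single_cell_flagged(self):
        est = granule_density([10], [10.0])
        assert est.mean == pytest.approx(1.0)
        assert est.sem == 0.0
        assert not est.sem_defined

    def test_two_cells_hand_arithmetic(self):
        # densities {2.0, 3.0}: mean 2.5, sem = sd(ddof=1)/sqrt(2) = 0.5
        est = granule_density([20, 30], [10.0, 10.0])
        assert est.mean == pytest.approx(2.5)
        assert est.sem == pytest.approx(0.5)
        assert est.sem_defined

    def test_length_mismatch_and_zero_area_rejected(self):
        with pytest.raises(ValueError):
            granule_density([1, 2], [1.0])
        with pytest.raises(ValueError):
            granule_density([1], [0.0])


class TestDistanceProfile:
    def test_all_zero_distances_in_first_bin(self):
        counts, edges, rel = distance_profile(np.zeros(5), 40.0, 120.0)
        assert counts.tolist() == [5, 0, 0]
        assert rel.tolist() == [1.0, 0.0, 0.0]

    def test_direct_binning(self):
        counts, edges, rel = distance_profile(np.array([10.0, 50.0, 90.0]), 40.0, 120.0)
        assert counts.tolist() == [1, 1, 1]
        assert edges.tolist() == [0.0, 40.0, 80.0, 120.0]

    def test_relative_frequencies_normalised(self):
        counts, _, rel = distance_profile(np.array([5.0, 45.0, 500.0]), 40.0, 120.0)
        assert counts.sum() == 2  # 500 nm lies beyond max_nm
        assert rel.sum() == pytest.approx(1.0)

    def test_mass_conservation_against_records(self):
        d = np.array([0.0, 39.9, 40.0, 119.9, 120.0, 250.0])
        counts, _, _ = distance_profile(d, 40.0, 120.0)
        assert counts.sum() == np.sum(d < 120.0)


class TestCompareGroups:
    def test_identical_samples_ks(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], kind="distribution")
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_disjoint_supports_ks_statistic_one(self):
        res = compare_groups([0, 0, 0, 0], [1, 1, 1, 1], kind="distribution")
        assert res.statistic == 1.0

    def test_ks_ecdf_supremum_enumeration(self):
        # ECDFs of {1,2,3} and {2,3,4} differ by at most 1/3
        res = compare_groups([1, 2, 3], [2, 3, 4], kind="distribution")
        assert res.statistic == pytest.approx(1 / 3)

    def test_t_test_requires_two_observations(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0], kind="mean")

    def test_t_test_detects_mean_shift(self, rng):
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(2.0, 1.0, 50)
        res = compare_groups(a, b, kind="mean")
        assert res.pvalue < 1e-6


class TestPopulationSummary:
    def test_histograms_sum_to_granule_count(self):
        spec = SceneSpec(seed=41, target_density_per_um2=2.3)
        truth = generate_scene(spec)
        records = measure_scene(
            truth.granule_instances, truth.image,
            membrane_polyline=truth.membrane_polyline,
        )
        summary = summarize_population([records], [truth.cytoplasm_area_um2()])
        assert summary.n_granules == len(records)
        assert summary.radius_hist[0].sum() == summary.n_granules
        assert summary.round_coeff_hist[0].sum() == summary.n_granules
        assert summary.n_cells == 1
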