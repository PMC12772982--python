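import numpy as np
import pytest

from cervhsi.consensus import pairwise_iou
from cervhsi.registration import (
    Homography,
    estimate_homography,
    project_points,
)
from cervhsi.spectral import absorbance, build_grid
from cervhsi.synthetic_data import (
    CohortSpec,
    ExaminerNoiseSpec,
    LesionRegion,
    PhantomSpec,
    generate_phantom_cube,
    generate_second_view,
    generate_subject_scene,
    rasterize_polygon,
    simulate_examiner_annotations,
)
from conftest import square_polygon


class TestRasterizePolygon:
    def test_square_pixel_centers(self):
        # even-odd rule, pixel center inside: square [1.5, 4.5] covers
        # integer centers 2..4 in both axes
        poly = square_polygon(3.0, 3.0, 1.5)
        mask = rasterize_polygon(poly, (7, 7))
        expected = np.zeros((7, 7), dtype=bool)
        expected[2:5, 2:5] = True
        np.testing.assert_array_equal(mask, expected)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            rasterize_polygon(np.array([[0, 0], [1, 1]]), (5, 5))


class TestGeneratePhantomCube:
    def test_zero_concentration_no_noise_gives_baseline_inside_disc(self, grid100):
        spec = PhantomSpec(
            image_height=32,
            image_width=32,
            wavelength_grid=grid100,
            disc_center=(16.0, 16.0),
            disc_radius=12.0,
            baseline_concentrations={"hbo2": 0.0, "hb": 0.0, "water": 0.0},
            noise_sd=0.0,
        )
        cube, truth = generate_phantom_cube(spec)
        base = spec.baseline_reflectance(grid100.centers)
        inside = truth.masks["healthy"]
        np.testing.assert_allclose(
            cube.reflectance[inside],
            np.broadcast_to(base, (int(inside.sum()), base.size)),
        )

    def test_seeded_determinism(self, small_phantom_spec):
        small_phantom_spec.noise_sd = 0.01
        a, _ = generate_phantom_cube(small_phantom_spec)
        b, _ = generate_phantom_cube(small_phantom_spec)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)

    def test_reflectance_bounded(self, small_phantom_spec):
        small_phantom_spec.noise_sd = 0.05
        cube, _ = generate_phantom_cube(small_phantom_spec)
        assert cube.reflectance.min() >= 0.0
        assert cube.reflectance.max() <= 1.0

    def test_lesion_absorbs_more_in_hemoglobin_window(self, small_phantom_spec, grid100):
        # oracle: compare mean absorbance in 530-590 nm between lesion and
        # healthy regions, computed directly from the rendered cube
        cube, truth = generate_phantom_cube(small_phantom_spec)
        idx = grid100.band_indices(530, 590)
        a = absorbance(cube.reflectance)[:, :, idx].mean(axis=2)
        lesion_mean = a[truth.masks["major"]].mean()
        healthy_mean = a[truth.masks["healthy"]].mean()
        assert lesion_mean > healthy_mean

    def test_multiplier_one_removes_contrast(self, small_phantom_spec, grid100):
        small_phantom_spec.lesion_regions[0].multipliers = {
            "hbo2": 1.0,
            "hb": 1.0,
            "water": 1.0,
        }
        cube, truth = generate_phantom_cube(small_phantom_spec)
        idx = grid100.band_indices(530, 590)
        a = absorbance(cube.reflectance)[:, :, idx].mean(axis=2)
        assert a[truth.masks["major"]].mean() == pytest.approx(
            a[truth.masks["healthy"]].mean(), abs=1e-9
        )

    def test_ground_truth_masks_disjoint(self, small_phantom_spec):
        _, truth = generate_phantom_cube(small_phantom_spec)
        assert not (truth.masks["major"] & truth.masks["healthy"]).any()

    def test_lesion_outside_disc_rejected(self, grid100):
        spec = PhantomSpec(
            image_height=32,
            image_width=32,
            wavelength_grid=grid100,
            disc_center=(16.0, 16.0),
            disc_radius=8.0,
            lesion_regions=[LesionRegion("major", square_polygon(28.0, 28.0, 3.0))],
        )
        with pytest.raises(ValueError, match="outside"):
            generate_phantom_cube(spec)

    def test_negative_concentration_rejected(self, grid100):
        spec = PhantomSpec(
            image_height=8,
            image_width=8,
            wavelength_grid=grid100,
            disc_center=(4.0, 4.0),
            disc_radius=3.0,
            baseline_concentrations={"water": -1.0},
        )
        with pytest.raises(ValueError):
            generate_phantom_cube(spec)


class TestSimulateExaminerAnnotations:
    def test_zero_noise_identity(self, small_phantom_spec):
        _, truth = generate_phantom_cube(small_phantom_spec)
        noise = ExaminerNoiseSpec(
            n_examiners=3,
            boundary_jitter_sd=0.0,
            dilation_bias_range=(0.0, 0.0),
            omission_probability=0.0,
        )
        sets = simulate_examiner_annotations(truth, noise)
        for s in sets:
            for cls, mask in truth.masks.items():
                np.testing.assert_array_equal(s.masks[cls], mask)

    def test_cardinality(self, small_phantom_spec):
        _, truth = generate_phantom_cube(small_phantom_spec)
        sets = simulate_examiner_annotations(truth, ExaminerNoiseSpec(n_examiners=5))
        assert len(sets) == 5
        assert len({s.examiner_id for s in sets}) == 5

    def test_omission_probability_one_drops_all_lesions(self, small_phantom_spec):
        _, truth = generate_phantom_cube(small_phantom_spec)
        sets = simulate_examiner_annotations(
            truth, ExaminerNoiseSpec(n_examiners=4, omission_probability=1.0)
        )
        assert all("major" not in s.masks for s in sets)

    def test_determinism(self, small_phantom_spec):
        _, truth = generate_phantom_cube(small_phantom_spec)
        noise = ExaminerNoiseSpec(n_examiners=3, seed=5)
        a = simulate_examiner_annotations(truth, noise)
        b = simulate_examiner_annotations(truth, noise)
        for s1, s2 in zip(a, b):
            for cls in s1.masks:
                np.testing.assert_array_equal(s1.masks[cls], s2.masks[cls])

    def test_more_jitter_lowers_mean_pairwise_iou(self, small_phantom_spec):
        # Monte-Carlo over 20 seeds with the IoU oracle
        _, truth = generate_phantom_cube(small_phantom_spec)

        def mean_iou(jitter_sd):
            vals = []
            for seed in range(20):
                sets = simulate_examiner_annotations(
                    truth,
                    ExaminerNoiseSpec(
                        n_examiners=3,
                        boundary_jitter_sd=jitter_sd,
                        dilation_bias_range=(0.0, 0.0),
                        seed=seed,
                    ),
                )
                for i in range(3):
                    for j in range(i + 1, 3):
                        v = pairwise_iou(sets[i].masks["major"], sets[j].masks["major"])
                        if v is not None:
                            vals.append(v)
            return np.mean(vals)

        assert mean_iou(4.0) < mean_iou(1.0)

    def test_empty_truth_rejected(self):
        from cervhsi.consensus import AnnotationSet

        truth = AnnotationSet("s", "truth", masks={"major": np.zeros((8, 8), bool)})
        with pytest.raises(ValueError, match="nonempty"):
            simulate_examiner_annotations(truth, ExaminerNoiseSpec())

    def test_invalid_omission_rejected(self, small_phantom_spec):
        _, truth = generate_phantom_cube(small_phantom_spec)
        with pytest.raises(ValueError):
            simulate_examiner_annotations(
                truth, ExaminerNoiseSpec(omission_probability=1.5)
            )


class TestGenerateSecondView:
    def test_identity_no_noise_landmarks_identical(self, small_phantom_spec):
        cube, _ = generate_phantom_cube(small_phantom_spec)
        _, lm = generate_second_view(
            cube, Homography.identity(), scale=1.0, noise_sd=0.0, seed=1
        )
        np.testing.assert_allclose(lm.src, lm.dst, atol=1e-9)

    def test_round_trip_recovers_h_true(self, small_phantom_spec):
        cube, _ = generate_phantom_cube(small_phantom_spec)
        H_true = Homography(
            np.array([[0.7, 0.02, 1.5], [-0.01, 0.68, -0.8], [1e-4, -5e-5, 1.0]])
        )
        _, lm = generate_second_view(cube, H_true, scale=1.5, noise_sd=0.0, seed=3)
        H_est = estimate_homography(lm)
        np.testing.assert_allclose(H_est.h, H_true.h, atol=1e-6)

    def test_exactly_four_noncollinear_landmarks(self, small_phantom_spec):
        cube, _ = generate_phantom_cube(small_phantom_spec)
        _, lm = generate_second_view(
            cube, Homography.identity(), n_landmarks=4, seed=2
        )
        assert len(lm) == 4
        # any 3 of the 4 source points span a triangle of nonzero area
        p = lm.src
        for i in range(4):
            tri = np.delete(p, i, axis=0)
            area2 = abs(
                (tri[1, 0] - tri[0, 0]) * (tri[2, 1] - tri[0, 1])
                - (tri[1, 1] - tri[0, 1]) * (tri[2, 0] - tri[0, 0])
            )
            assert area2 > 1e-6

    def test_output_scaled_resolution(self, small_phantom_spec):
        cube, _ = generate_phantom_cube(small_phantom_spec)
        rgb, _ = generate_second_view(cube, Homography.identity(), scale=2.0, seed=0)
        assert rgb.shape == (96, 96, 3)

    def test_singular_homography_rejected(self, small_phantom_spec):
        cube, _ = generate_phantom_cube(small_phantom_spec)
        with pytest.raises(ValueError):
            generate_second_view(cube, Homography(np.diag([1.0, 1.0, 0.0])), seed=0)


class TestCohortScenes:
    def test_scene_determinism(self):
        spec = CohortSpec(seed=11, n_subjects=1, image_height=40, image_width=40)
        a = generate_subject_scene(spec, 0)
        b = generate_subject_scene(spec, 0)
        np.testing.assert_array_equal(a.cube.reflectance, b.cube.reflectance)
        np.testing.assert_array_equal(a.landmarks.src, b.landmarks.src)
        for s1, s2 in zip(a.examiner_annotations, b.examiner_annotations):
            for cls in s1.masks:
                np.testing.assert_array_equal(s1.masks[cls], s2.masks[cls])

    def test_landmarks_consistent_with_true_homography(self):
        spec = CohortSpec(seed=4, n_subjects=1, image_height=40, image_width=40,
                          landmark_noise_sd=0.0)
        scene = generate_subject_scene(spec, 0)
        proj = project_points(scene.H_true, scene.landmarks.src)
        np.testing.assert_allclose(proj, scene.landmarks.dst, atol=1e-8)

    def test_higher_multiplier_increases_index_contrast_in_expectation(self):
        # monotonicity: raising the water multiplier must not decrease the
        # lesion-minus-healthy TWI gap, averaged over seeds
        from cervhsi.spectral import DEFAULT_INDEX_DEFS, compute_index

        def mean_gap(mult_range, seeds=3):
            gaps = []
            for seed in range(seeds):
                spec = CohortSpec(
                    seed=seed,
                    n_subjects=1,
                    image_height=40,
                    image_width=40,
                    water_multiplier=mult_range,
                )
                scene = generate_subject_scene(spec, 0)
                imap = compute_index(scene.cube, DEFAULT_INDEX_DEFS["TWI"])
                lesion = scene.truth.masks["major"]
                healthy = scene.truth.masks["healthy"]
                gaps.append(imap.values[lesion].mean() - imap.values[healthy].mean())
            return np.mean(gaps)

        assert mean_gap((2.0, 2.0)) > mean_gap((1.2, 1.2))
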