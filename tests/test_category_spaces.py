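"""Stimulus spaces, distributions, optimal bounds and set sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from catstrat import (
    CategoryDistribution,
    DecisionBound,
    StimulusSet,
    StimulusSpace,
    auditory_space,
    classify_with_bound,
    get_space,
    make_generalization_grid,
    normalized_to_physical,
    optimal_boundary,
    physical_to_normalized,
    sample_category_set,
    task_distributions,
    visual_space,
)
from catstrat.category_spaces import DegenerateDistributionsError


class TestSpacesAndTransform:
    def test_canonical_ranges(self):
        aud, vis = auditory_space(), visual_space()
        assert aud.x_range == (2.0, 14.8) and aud.y_range == (-0.38, 2.67)
        assert vis.x_range == (0.04, 0.072) and vis.y_range == (10.0, 104.0)

    def test_unit_square_maps_onto_ranges(self):
        aud = auditory_space()
        assert normalized_to_physical(aud, 0.0, 0.0) == (2.0, -0.38)
        assert normalized_to_physical(aud, 1.0, 1.0) == (14.8, 2.67)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_round_trip_identity(self, xn, yn):
        for space in (auditory_space(), visual_space()):
            xp, yp = normalized_to_physical(space, xn, yn)
            xb, yb = physical_to_normalized(space, xp, yp)
            assert abs(xb - xn) < 1e-12 and abs(yb - yn) < 1e-12

    def test_unknown_modality_rejected(self):
        with pytest.raises(ValueError):
            get_space("tactile")

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpace("auditory", "x", "y", (1.0, 1.0), (0.0, 1.0), "u", "v")


# Canonical per-category parameters: (mean_x, sd_x, mean_y, sd_y, cov).
EXPECTED_PARAMS = {
    ("auditory", "RB", "A"): (10.42, 1.58, 1.14, 0.66, 0.062),
    ("auditory", "RB", "B"): (5.59, 1.58, 1.14, 0.66, -0.062),
    ("auditory", "II", "A"): (10.0, 2.13, 0.72, 0.49, 0.43),
    ("auditory", "II", "B"): (6.62, 2.02, 1.53, 0.51, 0.43),
    ("visual", "RB", "A"): (0.061, 0.0039, 56.7, 20.4, 0.0048),
    ("visual", "RB", "B"): (0.049, 0.0039, 56.7, 20.4, -0.0048),
    ("visual", "II", "A"): (0.060, 0.0054, 43.2, 15.0, 0.034),
    ("visual", "II", "B"): (0.051, 0.0051, 68.5, 15.8, 0.034),
}


class TestTaskDistributions:
    @pytest.mark.parametrize("modality,task", [(m, t) for m in ("auditory", "visual") for t in ("RB", "II")])
    def test_canonical_parameters_verbatim(self, modality, task):
        dA, dB = task_distributions(modality, task)
        for dist in (dA, dB):
            mx, sx, my, sy, cov = EXPECTED_PARAMS[(modality, task, dist.label)]
            assert (dist.mean_x, dist.sd_x, dist.mean_y, dist.sd_y, dist.covariance) == (
                mx, sx, my, sy, cov,
            )
            assert dist.space.modality == modality

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            task_distributions("auditory", "XY")
        with pytest.raises(ValueError):
            task_distributions("gustatory", "RB")

    def test_invalid_distribution_parameters_rejected(self):
        space = auditory_space()
        with pytest.raises(ValueError):
            CategoryDistribution("A", "RB", space, 5, 1, -1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            CategoryDistribution("A", "RB", space, 5, 1, 1.0, 1.0, 2.0)


class TestDecisionBound:
    def test_unit_normal_constraint(self):
        b = DecisionBound(a=3.0, b=4.0, c=10.0)
        assert abs(b.a**2 + b.b**2 - 1.0) < 1e-12
        assert abs(b.c - 2.0) < 1e-12

    def test_point_on_bound_labeled_A(self):
        b = DecisionBound.vertical(0.5, positive_label="B")
        assert b.classify(np.array([0.5]), np.array([0.2]))[0] == "A"

    def test_flip_complements_accuracy(self, fixture_sets, fixture_bounds):
        sset = fixture_sets[("auditory", "II")]
        bound = fixture_bounds[("auditory", "II")]
        _, acc = classify_with_bound(bound, sset)
        _, acc_flipped = classify_with_bound(bound.flipped(), sset)
        assert acc + acc_flipped == pytest.approx(1.0, abs=1e-12)


class TestOptimalBoundary:
    def test_rb_midpoint_criteria_in_physical_units(self):
        aud = optimal_boundary(*task_distributions("auditory", "RB"))
        x_phys, _ = normalized_to_physical(auditory_space(), aud.criterion_x, 0.0)
        assert x_phys == pytest.approx((10.42 + 5.59) / 2, abs=1e-9)
        vis = optimal_boundary(*task_distributions("visual", "RB"))
        x_phys, _ = normalized_to_physical(visual_space(), vis.criterion_x, 0.0)
        assert x_phys == pytest.approx((0.061 + 0.049) / 2, abs=1e-9)

    def test_ii_bound_is_diagonal_and_unit_normal(self):
        b = optimal_boundary(*task_distributions("auditory", "II"))
        assert abs(b.a**2 + b.b**2 - 1.0) < 1e-12
        assert b.a != 0.0 and b.b != 0.0

    def test_mirror_symmetric_pair_bounds_at_zero(self):
        space = StimulusSpace("auditory", "x", "y", (-1.0, 1.0), (-1.0, 1.0), "u", "v")
        dA = CategoryDistribution("A", "RB", space, 0.5, 0.0, 0.2, 0.2, 0.0)
        dB = CategoryDistribution("B", "RB", space, -0.5, 0.0, 0.2, 0.2, 0.0)
        b = optimal_boundary(dA, dB)
        x_phys, _ = normalized_to_physical(space, b.criterion_x, 0.0)
        assert x_phys == pytest.approx(0.0, abs=1e-12)

    def test_identical_means_degenerate(self):
        space = auditory_space()
        dA = CategoryDistribution("A", "RB", space, 8.0, 1.0, 1.0, 0.5, 0.0)
        dB = CategoryDistribution("B", "RB", space, 8.0, 1.0, 1.0, 0.5, 0.0)
        with pytest.raises(DegenerateDistributionsError):
            optimal_boundary(dA, dB)

    @pytest.mark.parametrize("modality", ["auditory", "visual"])
    def test_rb_discriminant_matches_midpoint_criterion(self, modality):
        """With equal irrelevant-dimension means (and cancelling covariances),
        the II-style pooled discriminant reduces to the unidimensional midpoint."""
        dA, dB = task_distributions(modality, "RB")
        uni = optimal_boundary(dA, dB)
        muA, muB = dA.normalized_mean(), dB.normalized_mean()
        pooled = (dA.normalized_cov() + dB.normalized_cov()) / 2.0
        w = np.linalg.solve(pooled, muA - muB)
        mid = (muA + muB) / 2.0
        lda = DecisionBound(a=float(w[0]), b=float(w[1]), c=-float(w @ mid))
        assert lda.criterion_x == pytest.approx(uni.criterion_x, abs=1e-9)


class TestSampleCategorySet:
    def test_exact_overlap_and_composition(self, fixture_sets, fixture_bounds):
        for key, sset in fixture_sets.items():
            assert len(sset) == 200
            counts = pd.Series(sset.categories).value_counts()
            assert counts["A"] == 100 and counts["B"] == 100
            _, acc = classify_with_bound(fixture_bounds[key], sset)
            assert acc == 190 / 200

    def test_all_coordinates_within_ranges(self, fixture_sets):
        for (modality, task), sset in fixture_sets.items():
            space = get_space(modality)
            assert space.contains(sset.data["x_phys"], sset.data["y_phys"]).all()
            assert ((sset.x_norm >= 0) & (sset.x_norm <= 1)).all()

    def test_zero_overlap_target(self):
        dA, dB = task_distributions("auditory", "RB")
        sset = sample_category_set(dA, dB, 100, 0, seed=42)
        _, acc = classify_with_bound(optimal_boundary(dA, dB), sset)
        assert acc == 1.0

    def test_deterministic_given_seed(self):
        dA, dB = task_distributions("visual", "II")
        s1 = sample_category_set(dA, dB, 50, 5, seed=9)
        s2 = sample_category_set(dA, dB, 50, 5, seed=9)
        pd.testing.assert_frame_equal(s1.data, s2.data)

    def test_invalid_arguments(self):
        dA, dB = task_distributions("auditory", "RB")
        with pytest.raises(ValueError):
            sample_category_set(dA, dB, 0, 0, seed=1)
        with pytest.raises(ValueError):
            sample_category_set(dA, dB, 10, 21, seed=1)

    @pytest.mark.parametrize("seed", range(6))
    def test_sample_moments_track_population(self, seed):
        dA, dB = task_distributions("auditory", "RB")
        sset = sample_category_set(dA, dB, 100, 10, seed=seed)
        a = sset.data[sset.data["category"] == "A"]
        se = 1.58 / np.sqrt(100)
        assert abs(a["x_phys"].mean() - 10.42) <= 4 * se

    def test_csv_round_trip(self, tmp_path, fixture_sets):
        sset = fixture_sets[("auditory", "RB")]
        path = tmp_path / "set.csv"
        sset.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "id,task,modality,category,x_phys,y_phys,x_norm,y_norm"
        back = StimulusSet.from_csv(path)
        assert back.task == "RB" and back.space.modality == "auditory"
        pd.testing.assert_frame_equal(
            back.data.reset_index(drop=True), sset.data.reset_index(drop=True)
        )


class TestGeneralizationGrid:
    def test_grid_size_and_ranges(self, fixture_bounds):
        space = auditory_space()
        grid = make_generalization_grid(space, "RB", fixture_bounds[("auditory", "RB")])
        assert len(grid) == 64
        assert space.contains(grid.data["x_phys"], grid.data["y_phys"]).all()

    def test_two_by_two_grid_hits_corners(self, fixture_bounds):
        grid = make_generalization_grid(
            auditory_space(), "RB", fixture_bounds[("auditory", "RB")], n_side=2
        )
        corners = set(zip(grid.data["x_phys"], grid.data["y_phys"]))
        assert corners == {(2.0, -0.38), (2.0, 2.67), (14.8, -0.38), (14.8, 2.67)}

    def test_labels_match_bound(self, fixture_bounds):
        bound = fixture_bounds[("visual", "II")]
        grid = make_generalization_grid(visual_space(), "II", bound)
        assert (grid.categories == bound.classify(grid.x_norm, grid.y_norm)).all()

    def test_disjoint_from_training(self, fixture_sets, fixture_bounds):
        sset = fixture_sets[("auditory", "II")]
        grid = make_generalization_grid(
            auditory_space(), "II", fixture_bounds[("auditory", "II")], training_set=sset
        )
        train = set(zip(sset.x_norm, sset.y_norm))
        assert not train & set(zip(grid.x_norm, grid.y_norm))
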