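import numpy as np
import pytest

from filletbend.scene_sim import (
    CLASS_PRESETS,
    LABELS,
    SceneGeometry,
    cohort_seeds,
    generate_cohort,
    make_fillet_profile,
    simulate_pass,
)


class TestSceneGeometry:
    def test_reference_point_is_one_radius_below_edge(self, geom):
        row, col = geom.reference_point
        assert row == geom.belt_row + geom.roller_radius
        assert col == geom.edge_col

    @pytest.mark.parametrize(
        "kw",
        [
            {"arrival_col": 700},          # arrival past the edge
            {"departure_row": 100},        # departure above the belt
            {"roller_radius": 0.0},
            {"line_speed_px_per_frame": -1.0},
        ],
    )
    def test_invalid_geometry_rejected(self, kw):
        with pytest.raises(ValueError):
            SceneGeometry(**kw)

    def test_replace_returns_modified_copy(self, geom):
        fast = geom.replace(line_speed_px_per_frame=12.0)
        assert fast.line_speed_px_per_frame == 12.0
        assert geom.line_speed_px_per_frame == 6.0


class TestFilletProfile:
    def test_deterministic_given_seed(self):
        a = make_fillet_profile("normal", rng_seed=3)
        b = make_fillet_profile("normal", rng_seed=3)
        assert np.array_equal(a.heights, b.heights)
        assert a.rigidity == b.rigidity

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            make_fillet_profile("mystery", rng_seed=0)

    def test_profile_shape_invariants(self):
        p = make_fillet_profile("severe", rng_seed=5)
        assert p.heights.size == p.length_px
        assert p.heights.max() == p.max_thickness_px
        assert p.heights.min() >= 2
        # tail-first: the leading (j=0) quarter is thinner than the head quarter
        q = p.length_px // 4
        assert p.heights[:q].mean() < p.heights[-q:].mean()

    def test_rigidity_ordering_of_presets(self):
        assert (
            CLASS_PRESETS["normal"]["rigidity"]
            < CLASS_PRESETS["moderate"]["rigidity"]
            < CLASS_PRESETS["severe"]["rigidity"]
        )


class TestSimulatePass:
    def test_frames_and_masks_are_consistent(self, normal_pass, geom):
        assert len(normal_pass.frames) == len(normal_pass.truth_masks)
        for frame, mask in zip(normal_pass.frames.frames, normal_pass.truth_masks):
            assert frame.dtype == np.uint8
            assert frame.shape == (geom.image_h, geom.image_w)
            assert mask.dtype == bool and mask.shape == frame.shape
        assert 0 <= normal_pass.truth_arrival_frame < len(normal_pass.frames)
        assert normal_pass.truth_arrival_frame <= normal_pass.truth_departure_frame

    def test_truth_arrival_marks_first_contact_with_trigger_column(self, normal_pass, geom):
        i = normal_pass.truth_arrival_frame
        assert normal_pass.truth_masks[i][:, geom.arrival_col].any()
        if i > 0:
            assert not normal_pass.truth_masks[i - 1][:, geom.arrival_col].any()

    def test_flat_frame_rests_on_belt(self, noisefree_passes, geom):
        sim = noisefree_passes[0]
        mask = sim.truth_masks[sim.truth_arrival_frame]
        rows = np.nonzero(mask)[0]
        assert rows.max() == geom.belt_row - 1  # bottom row just above the belt surface

    def test_noisefree_intensities_are_exact(self, noisefree_passes):
        sim = noisefree_passes[0]
        frame = sim.frames[sim.truth_arrival_frame]
        mask = sim.truth_masks[sim.truth_arrival_frame]
        assert np.all(frame[mask] == 200)
        assert np.all(frame[~mask] == 10)

    def test_low_rigidity_dips_closer_to_axle(self, geom):
        """A flexible fillet's centroid approaches the axle more than a rigid one's."""
        ref = np.array(geom.reference_point)

        def min_centroid_distance(label):
            profile = make_fillet_profile(label, rng_seed=1)
            sim = simulate_pass(profile, geom, rng_seed=2, label=label, noise_sigma=0.0)
            best = np.inf
            for mask in sim.truth_masks:
                if mask.any():
                    rows, cols = np.nonzero(mask)
                    c = np.array([rows.mean(), cols.mean()])
                    best = min(best, float(np.hypot(*(c - ref))))
            return best

        assert min_centroid_distance("normal") < min_centroid_distance("severe")

    def test_oversized_profile_rejected(self, geom):
        profile = make_fillet_profile(
            "normal",
            rng_seed=0,
            presets={"normal": {"length": 2000, "length_sd": 0, "thickness": 70, "thickness_sd": 0, "rigidity": 40}},
        )
        with pytest.raises(ValueError):
            simulate_pass(profile, geom, rng_seed=0)


class TestCohort:
    def test_seeds_reproducible_and_balanced(self):
        a = cohort_seeds(4, master_seed=9)
        b = cohort_seeds(4, master_seed=9)
        assert a == b
        labels = [lab for lab, _, _ in a]
        assert labels.count("normal") == labels.count("moderate") == labels.count("severe") == 4

    def test_generate_cohort_one_per_class(self, geom):
        passes = generate_cohort(1, geom, master_seed=0)
        assert [p.label for p in passes] == list(LABELS)

    def test_invalid_cohort_size(self):
        with pytest.raises(ValueError):
            cohort_seeds(0, master_seed=0)
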