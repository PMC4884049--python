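"""Nearest-neighbour colour classification, mask cleanup and composition."""

import numpy as np
import pytest
from skimage.morphology import disk

import phenosalt as ps
from phenosalt.segmentation import LabelMask

from conftest import dilation_oracle, erosion_oracle, nn_oracle

TWO_CLASS = [((0, 255, 0), "plant"), ((0, 0, 255), "background")]


class TestClassifierTraining:
    def test_conflicting_duplicate_colour_rejected(self):
        with pytest.raises(ValueError, match="mapped to both"):
            ps.train_color_classifier(
                [((1, 2, 3), "plant"), ((1, 2, 3), "background")]
            )

    def test_redundant_duplicate_is_deduplicated(self):
        clf = ps.train_color_classifier(TWO_CLASS + [((0, 255, 0), "plant")])
        assert len(clf.samples_) == 2

    def test_no_samples_rejected(self):
        with pytest.raises(ValueError):
            ps.train_color_classifier([])

    def test_tie_priority_must_cover_all_classes(self):
        with pytest.raises(ValueError, match="omits"):
            ps.train_color_classifier(TWO_CLASS, tie_priority=["plant"])

    def test_background_first_in_default_priority(self):
        clf = ps.train_color_classifier(TWO_CLASS)
        assert clf.priority_[0] == "background"

    def test_out_of_range_colour_rejected(self):
        with pytest.raises(ValueError):
            ps.train_color_classifier([((300, 0, 0), "plant")])


class TestClassification:
    @pytest.mark.parametrize(
        "query,expected",
        [
            ((10, 240, 10), "plant"),  # distances ~18.7 vs ~346.4
            ((0, 255, 0), "plant"),  # exact training colour
            ((0, 0, 255), "background"),
            ((20, 20, 230), "background"),
        ],
    )
    def test_hand_computed_assignments(self, query, expected):
        clf = ps.train_color_classifier(TWO_CLASS)
        assert clf.predict(np.array([query]))[0] == expected

    def test_exact_tie_resolved_by_priority(self):
        # query (0,0,0) is equidistant from (2,0,0)-plant and (0,2,0)-background
        clf = ps.train_color_classifier(
            [((2, 0, 0), "plant"), ((0, 2, 0), "background")],
            tie_priority=["background", "plant"],
        )
        assert clf.predict(np.array([[0, 0, 0]]))[0] == "background"
        clf2 = ps.train_color_classifier(
            [((2, 0, 0), "plant"), ((0, 2, 0), "background")],
            tie_priority=["plant", "background"],
        )
        assert clf2.predict(np.array([[0, 0, 0]]))[0] == "plant"

    def test_two_by_two_image_against_hand_distances(self):
        clf = ps.train_color_classifier(TWO_CLASS)
        img = np.array(
            [[(10, 240, 10), (0, 0, 250)], [(5, 250, 5), (20, 20, 230)]],
            dtype=np.uint8,
        )
        mask = ps.classify_pixels(img, clf)
        plant = mask.class_index("plant")
        bg = mask.class_index("background")
        assert mask.labels.tolist() == [[plant, bg], [plant, bg]]

    def test_uniform_image_is_uniform_mask(self, rgb_classifier):
        img = np.full((5, 7, 3), (30, 160, 40), np.uint8)
        mask = ps.classify_pixels(img, rgb_classifier)
        assert mask.class_mask("plant").all()

    def test_label_histogram_partitions_image(self, rgb_classifier):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (13, 17, 3), dtype=np.uint8)
        counts = ps.classify_pixels(img, rgb_classifier).counts()
        assert sum(counts.values()) == 13 * 17

    def test_matches_brute_force_oracle_on_random_images(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = rng.integers(2, 6)
            samples = [tuple(rng.integers(0, 256, 3)) for _ in range(n)]
            labels = [rng.choice(["plant", "background", "frame"]) for _ in range(n)]
            if len(set(labels)) < 2:
                labels[0] = "plant" if labels[0] != "plant" else "background"
            clf = ps.train_color_classifier(list(zip(samples, labels)))
            img = rng.integers(0, 256, (12, 9, 3), dtype=np.uint8)
            got = ps.classify_pixels(img, clf)
            want = nn_oracle(img, clf.samples_,
                             [clf.priority_[i] for i in clf.sample_class_idx_],
                             clf.priority_)
            got_names = np.array(clf.priority_, dtype=object)[got.labels]
            assert (got_names == want).all()


class TestCleanMask:
    @staticmethod
    def _mask(arr, classes=("background", "plant")):
        return LabelMask(np.asarray(arr, int), classes)

    def test_zero_parameters_is_identity(self):
        rng = np.random.default_rng(1)
        m = self._mask(rng.integers(0, 2, (8, 8)))
        out = ps.clean_mask(m, erosion_radius=0, dilation_radius=0, min_size=0)
        assert (out.labels == m.labels).all()

    def test_size_filter_removes_isolated_pixel_keeps_block(self):
        arr = np.zeros((7, 7), int)
        arr[0, 6] = 1  # isolated pixel
        arr[2:5, 1:4] = 1  # 3x3 block
        out = ps.clean_mask(self._mask(arr), erosion_radius=0, dilation_radius=0,
                            min_size=2)
        assert out.class_mask("plant").sum() == 9
        assert not out.class_mask("plant")[0, 6]

    def test_opening_solid_square_against_morphology_oracle(self):
        arr = np.zeros((14, 14), int)
        arr[2:12, 2:12] = 1  # solid 10x10 square
        out = ps.clean_mask(self._mask(arr), erosion_radius=1, dilation_radius=1,
                            min_size=0)
        structure = disk(1).astype(bool)
        expected = dilation_oracle(
            erosion_oracle(arr.astype(bool), structure), structure
        )
        assert (out.class_mask("plant") == expected).all()
        assert out.class_mask("plant").sum() >= 64

    def test_anti_extensive_when_dilation_not_larger(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            arr = (rng.random((12, 12)) < 0.4).astype(int)
            m = self._mask(arr)
            out = ps.clean_mask(m, erosion_radius=1, dilation_radius=1, min_size=0)
            assert not (out.class_mask("plant") & ~m.class_mask("plant")).any()

    def test_width3_strokes_survive_default_opening_exactly(self):
        spec = ps.random_plant_spec(7, noise_sd=0)
        _, masks = ps.render_rgb_views(spec)
        truth = masks["side1"]
        m = LabelMask(truth.astype(int), ("background", "plant"))
        out = ps.clean_mask(m)  # defaults: opening radius 1, min_size 50
        assert (out.class_mask("plant") == truth).all()

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            ps.clean_mask(self._mask(np.zeros((3, 3), int)), erosion_radius=-1)


class TestCompose:
    @staticmethod
    def _mask(arr):
        return LabelMask(np.asarray(arr, int), ("background", "plant"))

    def test_union_bounding_box_of_two_components(self):
        arr = np.zeros((25, 10), int)
        arr[0:4, 0:3] = 1  # 12 px, rows 0-3
        arr[10:20, 5:8] = 1  # 30 px, rows 10-19
        obj = ps.compose_plant_object(self._mask(arr))
        assert obj.pixel_count == 42
        assert obj.height_px == 20
        assert obj.component_count_before_compose == 2

    def test_empty_mask_yields_flagged_empty_object(self):
        obj = ps.compose_plant_object(self._mask(np.zeros((4, 4), int)))
        assert obj.is_empty and obj.pixel_count == 0 and obj.height_px == 0
        assert obj.bounding_box is None

    def test_single_component_matches_its_own_stats(self):
        arr = np.zeros((9, 9), int)
        arr[3:6, 2:7] = 1
        obj = ps.compose_plant_object(self._mask(arr))
        assert obj.pixel_count == 15
        assert obj.bounding_box == (3, 2, 5, 6)
        assert obj.height_px == 3
        assert obj.component_count_before_compose == 1

    def test_composition_permutation_invariant(self):
        rng = np.random.default_rng(5)
        arr = (rng.random((16, 16)) < 0.3).astype(int)
        obj1 = ps.compose_plant_object(self._mask(arr))
        # flipping the image permutes component order but not the union stats
        obj2 = ps.compose_plant_object(self._mask(arr[::-1, ::-1].copy()))
        assert obj1.pixel_count == obj2.pixel_count
        assert obj1.component_count_before_compose == obj2.component_count_before_compose
        assert obj1.height_px == obj2.height_px
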