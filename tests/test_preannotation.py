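"""Thresholding, conversion to task annotations, propagation, and plugins."""

import numpy as np
import pytest

from annotassist.core import MaskAnnotation, SeedAnnotation, TaskKind
from annotassist.preannotation import (
    PredictorContract,
    binary_to_annotation,
    otsu_threshold,
    propagate_previous,
    run_predictor,
    threshold,
)
from annotassist.selection import SelectorKind
from annotassist.synthetic import BlobSpec, make_blobs


def otsu_bruteforce(image):
    """Independent oracle: scan all 256 candidate levels, recompute the
    between-class variance from scratch for the split (x <= t | x > t),
    return the smallest argmax."""
    x = image.ravel().astype(float)
    best_t, best_v = None, -1.0
    for t in range(256):
        lo, hi = x[x <= t], x[x > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / x.size, hi.size / x.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return best_t


class TestOtsu:
    def test_bimodal_partitions_at_variance_argmax(self):
        img = np.concatenate([np.full(50, 10), np.full(50, 200)]).astype(np.uint8)
        img = img.reshape(10, 10)
        t = otsu_threshold(img)
        assert t == otsu_bruteforce(img)
        fg = threshold(img, "otsu")
        assert fg.sum() == 50 and np.all(img[fg] == 200)

    def test_matches_bruteforce_on_random_images(self, rng):
        for _ in range(30):
            img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
            assert otsu_threshold(img) == otsu_bruteforce(img)

    def test_smallest_argmax_tiebreak(self):
        # two values: every t in [10, 200) splits identically; smallest distinct
        # level below the upper mode must be returned
        img = np.array([[10, 10], [200, 200]], dtype=np.uint8)
        assert otsu_threshold(img) == 10

    def test_constant_image_warns_and_yields_empty_foreground(self, caplog):
        img = np.full((8, 8), 42, dtype=np.uint8)
        with caplog.at_level("WARNING", logger="annotassist"):
            fg = threshold(img, "otsu")
        assert fg.sum() == 0
        assert any("constant" in r.message for r in caplog.records)

    def test_agrees_with_skimage_on_separable_images(self, rng):
        # independent cross-check: same foreground partition as the
        # library implementation on cleanly bimodal data
        from skimage.filters import threshold_otsu as sk_otsu

        for seed in range(5):
            img, *_ = make_blobs(BlobSpec(seed=seed))
            ours = img > otsu_threshold(img)
            theirs = img > sk_otsu(img)
            assert (ours != theirs).mean() < 0.01


class TestOtherThresholds:
    def test_constant_value(self):
        img = np.array([[10, 200], [10, 200]], dtype=np.uint8)
        assert threshold(img, "constant", value=100).mean() == pytest.approx(0.5)

    def test_percentile_median_on_ramp(self):
        ramp = np.arange(100, dtype=np.uint8).reshape(10, 10)
        # median of 0..99 is 49.5; foreground strictly above → 50 pixels
        fg = threshold(ramp, "percentile", q=50)
        assert fg.sum() == 50
        assert np.all(ramp[fg] > 49.5)

    def test_invert_flips_side(self):
        img = np.array([[10, 200]], dtype=np.uint8)
        assert threshold(img, "constant", value=100, invert=True).tolist() == [[True, False]]


class TestBinaryToAnnotation:
    def test_two_disjoint_squares(self):
        binary = np.zeros((10, 10), bool)
        binary[0:3, 0:3] = True
        binary[6:9, 6:9] = True
        ann = binary_to_annotation(binary, TaskKind.instance_segmentation)
        assert ann.instance_ids() == [1, 2]
        assert sorted(int((ann.labels == i).sum()) for i in (1, 2)) == [9, 9]

    def test_diagonal_touch_is_one_component_at_8conn(self):
        binary = np.zeros((6, 6), bool)
        binary[0:2, 0:2] = True
        binary[2:4, 2:4] = True  # touches only at the (1,1)-(2,2) diagonal
        ann = binary_to_annotation(binary, TaskKind.instance_segmentation)
        assert ann.instance_ids() == [1]
        ann4 = binary_to_annotation(binary, TaskKind.instance_segmentation, connectivity=4)
        assert ann4.instance_ids() == [1, 2]

    def test_seed_centroid_of_square(self):
        binary = np.zeros((5, 5), bool)
        binary[0:3, 0:3] = True
        ann = binary_to_annotation(binary, TaskKind.seed_detection)
        assert ann.points == [(1, 1)]

    def test_semantic_uses_fg_class(self):
        binary = np.array([[True, False]])
        ann = binary_to_annotation(binary, TaskKind.semantic_segmentation, fg_class=2)
        assert ann.labels.tolist() == [[2, 0]]

    def test_classification_is_an_error(self):
        with pytest.raises(ValueError, match="classification"):
            binary_to_annotation(np.zeros((2, 2), bool), TaskKind.classification)


class TestBlobRecovery:
    @pytest.mark.parametrize("n_blobs", [1, 4, 8])
    def test_otsu_components_recover_count_and_centers(self, n_blobs):
        for seed in range(5):
            img, inst, _, seeds = make_blobs(BlobSpec(n_blobs=n_blobs, seed=seed))
            fg = threshold(img, "otsu")
            ann = binary_to_annotation(fg, TaskKind.seed_detection)
            assert len(ann.points) == n_blobs
            for r, c in ann.points:
                d = min((r - tr) ** 2 + (c - tc) ** 2 for tr, tc in seeds.points)
                assert d <= 2  # within 1 px per axis of the true center

    def test_instance_labels_are_contiguous_from_one(self):
        img, _, _, _ = make_blobs(BlobSpec(n_blobs=6, seed=9))
        ann = binary_to_annotation(threshold(img, "otsu"), TaskKind.instance_segmentation)
        assert ann.instance_ids() == list(range(1, 7))


class TestPropagation:
    def test_copy_of_previous_mask(self):
        prev = MaskAnnotation(np.array([[1, 0], [0, 2]]), "instance")
        out = propagate_previous(prev, (2, 2))
        np.testing.assert_array_equal(out.labels, prev.labels)
        out.labels[0, 0] = 9  # deep copy: prev unchanged
        assert prev.labels[0, 0] == 1

    def test_first_frame_has_no_previous(self):
        with pytest.raises(ValueError, match="previous"):
            propagate_previous(None, (2, 2))

    def test_shape_mismatch(self):
        prev = MaskAnnotation(np.zeros((100, 100), int), "instance")
        with pytest.raises(ValueError, match="shape"):
            propagate_previous(prev, (80, 80))

    def test_requires_sequential_selector(self):
        prev = MaskAnnotation(np.zeros((2, 2), int), "instance")
        with pytest.raises(ValueError, match="sequential"):
            propagate_previous(prev, (2, 2), SelectorKind.random)


class TestPredictorPlugin:
    def test_valid_output_accepted_with_provenance(self):
        pred = PredictorContract(
            "dummy", "1.0", TaskKind.instance_segmentation,
            lambda im: MaskAnnotation(np.zeros(im.shape[:2], dtype=np.int64), "instance"))
        ann, prov = run_predictor(np.zeros((4, 4)), pred, TaskKind.instance_segmentation)
        assert prov == {"predictor": "dummy", "version": "1.0"}

    def test_wrong_shape_is_a_validation_error_naming_the_predictor(self):
        pred = PredictorContract(
            "badnet", "0.1", TaskKind.instance_segmentation,
            lambda im: MaskAnnotation(np.zeros((2, 2), dtype=np.int64), "instance"))
        with pytest.raises(ValueError, match="badnet"):
            run_predictor(np.zeros((4, 4)), pred, TaskKind.instance_segmentation)

    def test_threshold_wrapped_as_predictor_matches_direct_call(self):
        img, *_ = make_blobs(BlobSpec(seed=3))

        def predict(im):
            return binary_to_annotation(threshold(im, "otsu"), TaskKind.instance_segmentation)

        pred = PredictorContract("otsu-wrap", "1", TaskKind.instance_segmentation, predict)
        ann, _ = run_predictor(img, pred, TaskKind.instance_segmentation)
        direct = binary_to_annotation(threshold(img, "otsu"), TaskKind.instance_segmentation)
        np.testing.assert_array_equal(ann.labels, direct.labels)
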