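"""Sample-ordering strategies and the feature cache."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annotassist.core import ImageRecord
from annotassist.selection import (
    FeatureCache,
    cherry_order,
    default_extractor,
    extract_features,
    heterogeneity_order,
    load_cache,
    pairwise_dissimilarity,
    random_order,
    save_cache,
    sequential_order,
)


def rec(i, filename=None, annotated=False, h="0" * 64):
    return ImageRecord(id=i, filename=filename or f"{i}.png", height=4, width=4,
                       channels=1, content_hash=h, annotated=annotated)


class TestSequential:
    def test_alphabetic_by_filename(self):
        records = [rec("b"), rec("a"), rec("c")]
        assert sequential_order(records) == ["a", "b", "c"]

    def test_annotated_excluded(self):
        records = [rec("a", annotated=True), rec("b"), rec("c")]
        assert sequential_order(records) == ["b", "c"]

    def test_empty(self):
        assert sequential_order([]) == []


class TestRandom:
    def test_deterministic_for_same_seed(self):
        records = [rec(i) for i in "abcdef"]
        assert random_order(records, 42) == random_order(records, 42)

    def test_permutation_census_is_uniform(self):
        # all 6 permutations of 3 ids occur with frequency 1/6 within 5 sigma
        records = [rec(i) for i in "abc"]
        counts = {}
        n = 6000
        for seed in range(n):
            key = tuple(random_order(records, seed))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        p = 1 / 6
        sigma = (n * p * (1 - p)) ** 0.5
        for c in counts.values():
            assert abs(c - n * p) < 5 * sigma

    def test_single_record(self):
        assert random_order([rec("a")], 0) == ["a"]


class TestCherry:
    def test_picked_first_then_sequential(self):
        records = [rec(i) for i in "abc"]
        assert cherry_order(records, ["c"]) == ["c", "a", "b"]

    def test_empty_pick_is_sequential(self):
        records = [rec(i) for i in "abc"]
        assert cherry_order(records, []) == ["a", "b", "c"]

    def test_unknown_pick_named_in_error(self):
        with pytest.raises(KeyError, match="x"):
            cherry_order([rec("a")], ["x"])


class TestExtractor:
    def test_constant_image(self):
        vec = default_extractor(np.full((32, 32), 42, dtype=np.uint8))
        assert vec.shape == (96,)
        assert np.all(vec[:64] == 0.0)          # min-max of a constant block
        assert np.count_nonzero(vec[64:]) == 1  # all mass in one histogram bin
        assert vec[64:].sum() == pytest.approx(1.0)

    def test_deterministic(self, rng):
        img = rng.integers(0, 255, (40, 52), dtype=np.uint8)
        np.testing.assert_array_equal(default_extractor(img), default_extractor(img))

    def test_offset_invariance_of_downsample_part(self, rng):
        img = rng.integers(0, 200, (32, 32)).astype(np.float64)
        shifted = img + 30.0
        v1, v2 = default_extractor(img), default_extractor(shifted)
        np.testing.assert_allclose(v1[:64], v2[:64], atol=1e-12)

    def test_wrong_dimension_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            extract_features(np.zeros((4, 4)), lambda im: np.zeros(5), expected_dim=96)


class TestPairwiseDissimilarity:
    def test_orthogonal_cosine_is_one(self):
        D = pairwise_dissimilarity([np.array([1.0, 0]), np.array([0, 1.0])], "cosine")
        assert D[0, 1] == pytest.approx(1.0)

    def test_l2_345(self):
        D = pairwise_dissimilarity([np.array([0.0, 0]), np.array([3.0, 4.0])], "l2")
        assert D[0, 1] == pytest.approx(5.0)

    @pytest.mark.parametrize("metric", ["l2", "cosine"])
    def test_identical_vectors_zero(self, metric):
        v = np.array([2.0, 3.0])
        D = pairwise_dissimilarity([v, v], metric)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_vector_under_cosine_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            pairwise_dissimilarity([np.zeros(2), np.array([3.0, 4.0])], "cosine")

    def test_symmetric_nonneg_zero_diagonal(self, rng):
        X = rng.normal(size=(6, 3))
        D = pairwise_dissimilarity(list(X), "l2")
        np.testing.assert_allclose(D, D.T, atol=1e-9)
        assert np.all(np.diag(D) == 0) and np.all(D >= 0)


def brute_force_maxmin_order(dissim, ids, annotated_ids=()):
    """Independent max-min farthest-point oracle: plain Python loops.

    At each step, scan every remaining id and compute its minimum distance to
    the reference set by explicit iteration; pick the max, ties to the
    lexicographically smallest.
    """
    index = {i: k for k, i in enumerate(ids)}
    annotated = [i for i in annotated_ids if i in index]
    remaining = sorted(i for i in ids if i not in set(annotated))
    ordered = []
    if not annotated and remaining:
        ordered.append(remaining.pop(0))
    while remaining:
        scores = {}
        for cand in remaining:
            dmin = min(
                dissim[index[cand]][index[ref]] for ref in annotated + ordered
            )
            scores[cand] = dmin
        best = max(scores.values())
        pick = min(c for c, s in scores.items() if s == best)
        ordered.append(pick)
        remaining.remove(pick)
    return ordered


class TestHeterogeneity:
    def test_1d_features_ordering(self):
        # features a:0, b:1, c:10 — after seeding with a, c is farthest
        feats = [np.array([0.0]), np.array([1.0]), np.array([10.0])]
        D = pairwise_dissimilarity(feats, "l2")
        assert heterogeneity_order(D, ["a", "b", "c"]) == ["a", "c", "b"]

    def test_annotated_seedset(self):
        # annotated c at 10; a (0) is farther from c than b (1)
        feats = [np.array([0.0]), np.array([1.0]), np.array([10.0])]
        D = pairwise_dissimilarity(feats, "l2")
        assert heterogeneity_order(D, ["a", "b", "c"], ["c"]) == ["a", "b"]

    def test_all_identical_is_lexicographic(self):
        feats = [np.array([1.0, 2.0])] * 4
        D = pairwise_dissimilarity(feats, "l2")
        assert heterogeneity_order(D, ["d", "b", "a", "c"]) == ["a", "b", "c", "d"]

    def test_first_pick_is_argmax_of_min_distance_to_annotated(self, rng):
        for _ in range(20):
            X = rng.normal(size=(6, 3))
            D = pairwise_dissimilarity(list(X), "l2")
            ids = [f"i{k}" for k in range(6)]
            annotated = ids[:2]
            order = heterogeneity_order(D, ids, annotated)
            expected_first = max(
                ids[2:], key=lambda i: (min(D[ids.index(i), 0], D[ids.index(i), 1]), )
            )
            assert order[0] == expected_first

    @settings(max_examples=60, deadline=None)
    @given(
        st.integers(2, 8).flatmap(
            lambda n: st.tuples(
                st.just(n),
                st.lists(
                    st.lists(st.floats(-5, 5), min_size=2, max_size=4),
                    min_size=n, max_size=n,
                ).filter(lambda vs: len({len(v) for v in vs}) == 1),
                st.integers(0, 1),  # metric selector
                st.integers(0, 2),  # number of annotated
            )
        )
    )
    def test_matches_bruteforce_oracle(self, args):
        n, vectors, metric_i, n_ann = args
        X = [np.asarray(v) for v in vectors]
        metric = ["l2", "cosine"][metric_i]
        if metric == "cosine" and any(np.linalg.norm(v) == 0 for v in X):
            return
        D = pairwise_dissimilarity(X, metric)
        ids = [f"id{k:02d}" for k in range(n)]
        annotated = ids[:min(n_ann, n - 1)]
        assert heterogeneity_order(D, ids, annotated) == \
            brute_force_maxmin_order(D, ids, annotated)

    def test_invariant_to_record_shuffling(self, rng):
        X = rng.normal(size=(7, 3))
        ids = [f"x{k}" for k in range(7)]
        D = pairwise_dissimilarity(list(X), "l2")
        base = heterogeneity_order(D, ids)
        perm = rng.permutation(7)
        Dp = D[np.ix_(perm, perm)]
        ids_p = [ids[i] for i in perm]
        assert heterogeneity_order(Dp, ids_p) == base


class TestFeatureCache:
    def test_roundtrip(self, tmp_path):
        cache = FeatureCache("downsample8x8+hist32", "l2")
        cache.put("hashA", np.array([0.123456789, 1.0]))
        save_cache(cache, tmp_path / "c.json")
        back = load_cache(tmp_path / "c.json")
        assert back.extractor_id == cache.extractor_id
        np.testing.assert_allclose(back.get("hashA"), [0.123456789, 1.0], atol=1e-9)

    def test_modified_image_entry_is_stale(self):
        cache = FeatureCache("e", "l2", {"oldhash": [1.0]})
        records = [rec("a", h="newhash")]
        assert cache.stale_entries(records) == ["a"]

    def test_metric_mismatch_is_stale(self):
        cache = FeatureCache("e", "l2")
        assert cache.stale_for("e", "cosine")
        assert not cache.stale_for("e", "l2")

    def test_corrupted_file_is_a_parse_error(self, tmp_path):
        (tmp_path / "bad.json").write_text("{nope")
        with pytest.raises(ValueError, match="corrupted"):
            load_cache(tmp_path / "bad.json")
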