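"""Sample-ordering strategies deciding which image is annotated next.

Four selectors: sequential (alphabetic by filename), random (seeded uniform
permutation), cherry-picker (a user-chosen prefix), and heterogeneity sampling
(greedy farthest-point / k-center ordering over pairwise feature
dissimilarities). Feature vectors are persisted in an external JSON cache
keyed by image content hash, so renamed files keep their entries and modified
files invalidate them.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import ImageRecord


class SelectorKind(str, enum.Enum):
    sequential = "sequential"
    random = "random"
    cherry = "cherry"
    heterogeneity = "heterogeneity"


def _unannotated(records: Sequence[ImageRecord]) -> list[ImageRecord]:
    return [r for r in records if not r.annotated]


def sequential_order(records: Sequence[ImageRecord]) -> list[str]:
    """Ids of unannotated images, sorted lexicographically by filename."""
    return [r.id for r in sorted(_unannotated(records), key=lambda r: r.filename)]


def random_order(records: Sequence[ImageRecord], seed: int) -> list[str]:
    """Seeded uniform permutation of the unannotated ids."""
    ids = sequential_order(records)  # canonical base order for determinism
    rng = np.random.default_rng(seed)
    return [ids[i] for i in rng.permutation(len(ids))]


def cherry_order(records: Sequence[ImageRecord], picked_ids: Sequence[str]) -> list[str]:
    """User-picked ids first (in the given order), then alphabetic remainder."""
    known = {r.id for r in records}
    for pid in picked_ids:
        if pid not in known:
            raise KeyError(f"picked id {pid!r} is not in the project")
    picked = list(picked_ids)
    rest = [i for i in sequential_order(records) if i not in set(picked)]
    unann = {r.id for r in _unannotated(records)}
    return [i for i in picked if i in unann] + rest


# ---------------------------------------------------------------------------
# Feature extraction

DEFAULT_EXTRACTOR_ID = "downsample8x8+hist32"
DEFAULT_DIM = 96


def default_extractor(image: np.ndarray) -> np.ndarray:
    """Built-in deterministic feature extractor, d = 96.

    Concatenates (i) the image downsampled to 8x8 grayscale, min-max
    normalized to [0, 1] (constant images map to zeros), and (ii) a 32-bin
    intensity histogram, L1-normalized.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    h, w = arr.shape
    # block-mean downsample to 8x8 via bin assignment (robust to any h, w)
    ri = np.minimum((np.arange(h) * 8) // h, 7)
    ci = np.minimum((np.arange(w) * 8) // w, 7)
    sums = np.zeros((8, 8))
    counts = np.zeros((8, 8))
    for block_r in range(8):
        rows = arr[ri == block_r]
        for block_c in range(8):
            block = rows[:, ci == block_c]
            sums[block_r, block_c] = block.sum()
            counts[block_r, block_c] = block.size
    small = sums / np.maximum(counts, 1)
    lo, hi = small.min(), small.max()
    ds = (small - lo) / (hi - lo) if hi > lo else np.zeros_like(small)
    hist, _ = np.histogram(arr, bins=32, range=(arr.min(), max(arr.max(), arr.min() + 1)))
    hist = hist.astype(np.float64)
    hist /= max(hist.sum(), 1.0)
    return np.concatenate([ds.ravel(), hist])


def extract_features(
    image: np.ndarray,
    extractor: Callable[[np.ndarray], np.ndarray] = default_extractor,
    expected_dim: int | None = None,
) -> np.ndarray:
    """Run a feature-extractor plugin and check its contract."""
    vec = np.asarray(extractor(image), dtype=np.float64)
    if vec.ndim != 1:
        raise ValueError("feature extractor must return a 1-D vector")
    if expected_dim is not None and vec.shape[0] != expected_dim:
        raise ValueError(
            f"extractor returned dimension {vec.shape[0]}, expected {expected_dim}"
        )
    return vec


# ---------------------------------------------------------------------------
# Pairwise dissimilarity


def pairwise_dissimilarity(vectors: Sequence[np.ndarray], metric: str) -> np.ndarray:
    """n x n symmetric dissimilarity matrix with zero diagonal.

    ``l2`` is the Euclidean distance; ``cosine`` is 1 - cos(u, v) (zero
    vectors are rejected, the angle being undefined).
    """
    X = np.asarray(list(vectors), dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 feature vectors of equal dimension")
    if metric == "l2":
        D = squareform(pdist(X, metric="euclidean"))
    elif metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero feature vector is not allowed under cosine")
        D = squareform(pdist(X, metric="cosine"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return np.maximum((D + D.T) / 2.0, 0.0)  # enforce exact symmetry


def heterogeneity_order(
    dissim: np.ndarray,
    ids: Sequence[str],
    annotated_ids: Sequence[str] = (),
) -> list[str]:
    """Greedy farthest-point (max-min) ordering of the unannotated ids.

    Each pick maximizes its minimum dissimilarity to the annotated images
    plus everything already ordered. With nothing annotated, the sequence is
    seeded with the lexicographically smallest id. Ties break
    lexicographically.
    """
    ids = list(ids)
    index = {i: k for k, i in enumerate(ids)}
    annotated = [i for i in annotated_ids if i in index]
    remaining = sorted(i for i in ids if i not in set(annotated))
    if not remaining:
        return []

    ordered: list[str] = []
    if not annotated:
        ordered.append(remaining.pop(0))  # lexicographically smallest seeds

    reference = [index[i] for i in annotated + ordered]
    while remaining:
        best_id, best_score = None, -np.inf
        for cand in remaining:  # remaining is sorted: first max wins ties
            score = float(dissim[index[cand], reference].min())
            if score > best_score:
                best_id, best_score = cand, score
        ordered.append(best_id)  # type: ignore[arg-type]
        remaining.remove(best_id)
        reference.append(index[best_id])
    return ordered


# ---------------------------------------------------------------------------
# Feature cache


@dataclass
class FeatureCache:
    """Persisted feature vectors keyed by image content hash."""

    extractor_id: str
    metric: str
    entries: dict[str, list[float]] = field(default_factory=dict)
    ordering: list[str] | None = None

    def __post_init__(self) -> None:
        dims = {len(v) for v in self.entries.values()}
        if len(dims) > 1:
            raise ValueError("cache entries have inconsistent dimensions")

    def get(self, content_hash: str) -> np.ndarray | None:
        v = self.entries.get(content_hash)
        return None if v is None else np.asarray(v, dtype=np.float64)

    def put(self, content_hash: str, vector: np.ndarray) -> None:
        self.entries[content_hash] = [float(x) for x in np.asarray(vector).ravel()]

    def stale_for(self, extractor_id: str, metric: str) -> bool:
        """True if this cache was built under a different configuration."""
        return self.extractor_id != extractor_id or self.metric != metric

    def stale_entries(self, records: Sequence[ImageRecord]) -> list[str]:
        """Image ids whose current content hash has no cache entry."""
        return [r.id for r in records if r.content_hash not in self.entries]


def save_cache(cache: FeatureCache, path: Union[str, Path]) -> None:
    payload = {
        "extractor_id": cache.extractor_id,
        "metric": cache.metric,
        "entries": cache.entries,
        "ordering": cache.ordering,
    }
    Path(path).write_text(json.dumps(payload))


def load_cache(path: Union[str, Path]) -> FeatureCache:
    try:
        payload = json.loads(Path(path).read_text())
        return FeatureCache(
            extractor_id=payload["extractor_id"],
            metric=payload["metric"],
            entries=payload.get("entries", {}),
            ordering=payload.get("ordering"),
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"corrupted feature cache {path}: {exc}") from exc


def order_by_heterogeneity(
    records: Sequence[ImageRecord],
    images: dict[str, np.ndarray],
    metric: str = "l2",
    cache: FeatureCache | None = None,
    extractor: Callable[[np.ndarray], np.ndarray] = default_extractor,
    extractor_id: str = DEFAULT_EXTRACTOR_ID,
) -> tuple[list[str], FeatureCache]:
    """End-to-end heterogeneity sampling with cache reuse.

    Stale caches (different extractor or metric) are discarded; entries whose
    content hash no longer matches are recomputed.
    """
    if cache is None or cache.stale_for(extractor_id, metric):
        cache = FeatureCache(extractor_id=extractor_id, metric=metric)
    recs = sorted(records, key=lambda r: r.id)
    vectors = []
    for r in recs:
        vec = cache.get(r.content_hash)
        if vec is None:
            vec = extract_features(images[r.id], extractor)
            cache.put(r.content_hash, vec)
        vectors.append(vec)
    dissim = pairwise_dissimilarity(vectors, metric)
    ids = [r.id for r in recs]
    annotated = [r.id for r in recs if r.annotated]
    order = heterogeneity_order(dissim, ids, annotated)
    cache.ordering = order
    return order, cache
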