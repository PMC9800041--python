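"""Image conditioning before annotation, applied as a recorded pipeline.

Steps: intensity normalization (min-max or percentile-clipped), denoising
(gaussian / median, reflect padding), resampling (nearest / bilinear), and
region crops. Each application is recorded in a provenance log so the output
can be reproduced byte-for-byte from the raw image.

Masks are never normalized or denoised, and are resampled nearest-only; crops
apply to images, masks, and seed points alike (seed coordinates shift, seeds
outside the region are dropped). Multi-channel images are normalized
per-channel.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .core import MaskAnnotation, SeedAnnotation


def array_hash(arr: np.ndarray) -> str:
    """SHA-256 over an array's shape, dtype, and raw bytes."""
    h = hashlib.sha256()
    arr = np.ascontiguousarray(arr)
    h.update(str(arr.shape).encode())
    h.update(str(arr.dtype).encode())
    h.update(arr.tobytes())
    return h.hexdigest()


def normalize(
    image: np.ndarray, mode: str = "minmax", p_low: float = 0.0, p_high: float = 100.0
) -> np.ndarray:
    """Scale intensities into [0, 1].

    ``minmax``: (x - min) / (max - min). ``percentile``: clip to the
    [p_low, p_high] percentile range (linear-interpolation definition) and
    min-max the clipped values. A constant image maps to all zeros.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:  # per-channel
        return np.stack(
            [normalize(arr[..., c], mode, p_low, p_high) for c in range(arr.shape[2])],
            axis=2,
        )
    if mode == "minmax":
        lo, hi = arr.min(), arr.max()
    elif mode == "percentile":
        if not (0 <= p_low < p_high <= 100):
            raise ValueError("need 0 <= p_low < p_high <= 100")
        lo, hi = np.percentile(arr, [p_low, p_high])
        arr = np.clip(arr, lo, hi)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if hi <= lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def denoise(image: np.ndarray, method: str, size: float) -> np.ndarray:
    """Gaussian (sigma = size) or median (odd window = size) filtering."""
    arr = np.asarray(image, dtype=np.float64)
    if method == "gaussian":
        if size <= 0:
            raise ValueError("gaussian sigma must be > 0")
        if arr.ndim == 3:
            return np.stack(
                [ndimage.gaussian_filter(arr[..., c], sigma=size, mode="reflect")
                 for c in range(arr.shape[2])], axis=2)
        return ndimage.gaussian_filter(arr, sigma=size, mode="reflect")
    if method == "median":
        size = int(size)
        if size < 1 or size % 2 == 0:
            raise ValueError("median window must be odd and >= 1")
        if size == 1:
            return arr.copy()
        if arr.ndim == 3:
            return np.stack(
                [ndimage.median_filter(arr[..., c], size=size, mode="reflect")
                 for c in range(arr.shape[2])], axis=2)
        return ndimage.median_filter(arr, size=size, mode="reflect")
    raise ValueError(f"unknown denoise method {method!r}")


def resample(
    image: np.ndarray,
    scale: float | None = None,
    target: tuple[int, int] | None = None,
    interpolation: str = "bilinear",
    is_mask: bool = False,
) -> np.ndarray:
    """Resize by scale factor or to an explicit (height, width).

    Masks must use nearest interpolation so no new label values appear.
    """
    arr = np.asarray(image)
    if (scale is None) == (target is None):
        raise ValueError("give exactly one of scale or target")
    if scale is not None:
        if scale <= 0:
            raise ValueError("scale must be > 0")
        target = (max(1, round(arr.shape[0] * scale)), max(1, round(arr.shape[1] * scale)))
    th, tw = target  # type: ignore[misc]
    if th < 1 or tw < 1:
        raise ValueError("target dimensions must be >= 1")
    if is_mask and interpolation != "nearest":
        raise ValueError("masks must be resampled with nearest interpolation")
    order = {"nearest": 0, "bilinear": 1}[interpolation]
    out_shape = (th, tw) + arr.shape[2:]
    out = _sk_resize(arr, out_shape, order=order, preserve_range=True, anti_aliasing=False)
    return out.astype(arr.dtype) if (is_mask or order == 0) else out


Region = tuple[int, int, int, int]  # r0, c0, r1, c1 — half-open


def _check_region(region: Region, shape: tuple[int, int]) -> None:
    r0, c0, r1, c1 = region
    h, w = shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"region {region} empty or outside image {h}x{w}")


def crop(image: np.ndarray, region: Region) -> np.ndarray:
    """Half-open crop [r0, r1) x [c0, c1)."""
    _check_region(region, image.shape[:2])
    r0, c0, r1, c1 = region
    return np.asarray(image)[r0:r1, c0:c1].copy()


def crop_mask(mask: MaskAnnotation, region: Region) -> MaskAnnotation:
    return MaskAnnotation(crop(mask.labels, region), mask.semantics)


def crop_seeds(seeds: SeedAnnotation, region: Region) -> SeedAnnotation:
    """Shift seed coordinates into the crop frame; drop seeds outside it."""
    r0, c0, r1, c1 = region
    points, classes = [], []
    src_classes = seeds.classes or [None] * len(seeds.points)
    for (r, c), cls in zip(seeds.points, src_classes):
        if r0 <= r < r1 and c0 <= c < c1:
            points.append((r - r0, c - c0))
            classes.append(cls)
    has_cls = seeds.classes is not None
    return SeedAnnotation(points, classes if has_cls else None)


# ---------------------------------------------------------------------------
# Recorded pipelines


@dataclass
class PreprocSpec:
    """Ordered list of preprocessing steps, each {'op': ..., **params}."""

    steps: list[dict] = field(default_factory=list)

    VALID_OPS = ("normalize", "denoise", "resample", "crop")

    def __post_init__(self) -> None:
        for s in self.steps:
            if s.get("op") not in self.VALID_OPS:
                raise ValueError(f"unknown preprocessing op {s.get('op')!r}")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PreprocSpec":
        return cls(yaml.safe_load(Path(path).read_text())["steps"])

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump({"steps": self.steps}, sort_keys=False))


def apply_step(image: np.ndarray, step: dict) -> np.ndarray:
    op = step["op"]
    if op == "normalize":
        return normalize(image, step.get("mode", "minmax"),
                         step.get("p_low", 0.0), step.get("p_high", 100.0))
    if op == "denoise":
        return denoise(image, step["method"], step["size"])
    if op == "resample":
        return resample(image, scale=step.get("scale"),
                        target=tuple(step["target"]) if "target" in step else None,
                        interpolation=step.get("interpolation", "bilinear"))
    if op == "crop":
        return crop(image, tuple(step["region"]))
    raise ValueError(f"unknown op {op!r}")


@dataclass
class ProvenanceLog:
    """Append-only record of applied steps per image, with array hashes."""

    records: list[dict] = field(default_factory=list)

    def append(self, image_id: str, steps: Sequence[dict],
               input_hash: str, output_hash: str) -> None:
        self.records.append({
            "image_id": image_id,
            "steps": list(steps),
            "input_hash": input_hash,
            "output_hash": output_hash,
        })

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.records, indent=1))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ProvenanceLog":
        return cls(json.loads(Path(path).read_text()))


def apply_pipeline(
    image: np.ndarray,
    spec: PreprocSpec,
    image_id: str = "image",
    log: ProvenanceLog | None = None,
) -> np.ndarray:
    """Apply every step in order, recording provenance if a log is given."""
    out = np.asarray(image)
    in_hash = array_hash(out)
    for step in spec.steps:
        out = apply_step(out, step)
    if log is not None:
        log.append(image_id, spec.steps, in_hash, array_hash(out))
    return out


def replay(image: np.ndarray, record: dict) -> np.ndarray:
    """Re-run a provenance record; raises if hashes do not reproduce."""
    if array_hash(np.asarray(image)) != record["input_hash"]:
        raise ValueError("input image does not match the recorded input hash")
    out = apply_pipeline(image, PreprocSpec(record["steps"]))
    if array_hash(out) != record["output_hash"]:
        raise ValueError("replay did not reproduce the recorded output hash")
    return out
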