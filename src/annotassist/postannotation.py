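"""Automated cleanup of user annotations, with a traceable before/after diff.

Recurring annotation errors — holes inside segments and small noisy
fragments — are corrected by hole filling, small-object removal, and
morphological opening/closing. Every correction is summarized in an
``AnnotationDiff`` the user reviews before accepting: accept keeps the
processed annotation, reject keeps the raw one.

Instance masks are processed one instance at a time against background, so
morphology can never merge two instances or bleed labels between them.
Holes are background regions 4-connected among themselves but not reaching
the image border (foreground is treated 8-connected, the complementary
pairing). For classification, ambiguous crisp labels can be softened into a
two-class fuzzy distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml
from scipy import ndimage

from .core import ClassAnnotation, MaskAnnotation


def disk_footprint(radius: int) -> np.ndarray:
    """Rasterized disk: pixels within Euclidean distance radius + 0.5 of the
    center (radius 1 therefore includes the diagonal neighbors)."""
    rr, cc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return np.hypot(rr, cc) <= radius + 0.5

_BG_STRUCTURE = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
_FG_STRUCTURE = ndimage.generate_binary_structure(2, 2)  # 8-connectivity


def _labels_present(mask: MaskAnnotation) -> list[int]:
    return [int(v) for v in np.unique(mask.labels) if v > 0]


def fill_holes(mask: MaskAnnotation) -> MaskAnnotation:
    """Assign enclosed background pixels the label of the enclosing segment.

    A hole is background not 4-connected to the image border. Processed per
    label value (per instance for instance masks); filled pixels only ever
    claim true background, never another segment.
    """
    out = mask.labels.copy()
    for lab in _labels_present(mask):
        binary = mask.labels == lab
        filled = ndimage.binary_fill_holes(binary, structure=_BG_STRUCTURE)
        out[filled & (out == 0)] = lab
    return MaskAnnotation(out, mask.semantics)


def remove_small(mask: MaskAnnotation, min_area: int) -> MaskAnnotation:
    """Delete every connected component smaller than ``min_area`` pixels.

    Components are taken per instance id for instance masks and per
    8-connected component of each class for semantic masks.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    out = mask.labels.copy()
    for lab in _labels_present(mask):
        binary = mask.labels == lab
        if mask.semantics == "instance":
            if int(binary.sum()) < min_area:
                out[binary] = 0
        else:
            comp, k = ndimage.label(binary, structure=_FG_STRUCTURE)
            sizes = ndimage.sum_labels(binary, comp, index=np.arange(1, k + 1))
            for i, size in enumerate(sizes, start=1):
                if size < min_area:
                    out[comp == i] = 0
    return MaskAnnotation(out, mask.semantics)


def morph(mask: MaskAnnotation, op: str, radius: int) -> MaskAnnotation:
    """Binary opening/closing with a disk footprint, per label/instance.

    Each label is processed against background only: pixels gained by a
    closing are written only where the mask is background, so neighboring
    instances keep their identity.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if op not in ("open", "close"):
        raise ValueError(f"unknown morphological op {op!r}")
    footprint = disk_footprint(radius)
    out = mask.labels.copy()
    for lab in _labels_present(mask):
        binary = mask.labels == lab
        if op == "open":
            new = ndimage.binary_opening(binary, structure=footprint)
        else:
            new = ndimage.binary_closing(binary, structure=footprint)
        out[binary & ~new] = 0
        out[new & (out == 0)] = lab
    return MaskAnnotation(out, mask.semantics)


def fuzzify(label: str, secondary: str, weight: float, class_names: list[str]) -> ClassAnnotation:
    """Soften a crisp label into a two-class mixture: {label: 1-w, secondary: w}."""
    for name in (label, secondary):
        if name not in class_names:
            raise ValueError(f"unknown class {name!r}")
    if not (0.0 <= weight <= 1.0):
        raise ValueError("weight must lie in [0, 1]")
    if label == secondary:
        return ClassAnnotation({label: 1.0})
    dist = {label: 1.0 - weight, secondary: weight}
    return ClassAnnotation({k: v for k, v in dist.items() if v > 0.0})


# ---------------------------------------------------------------------------
# Diff


@dataclass
class AnnotationDiff:
    """Pixel- and segment-level accounting of a post-processing step.

    Carries the full sparse patch (changed pixels with old and new values) so
    the processed mask can be reconstructed from the raw one, and vice versa.
    """

    n_pixels_changed: int
    per_label_added: dict[int, int]
    per_label_removed: dict[int, int]
    segments_removed: list[int]
    segments_added: list[int]
    patch: list[tuple[int, int, int, int]] = field(default_factory=list)  # r, c, old, new

    @property
    def is_empty(self) -> bool:
        return self.n_pixels_changed == 0

    def summary(self) -> dict:
        return {
            "n_pixels_changed": self.n_pixels_changed,
            "per_label_added": self.per_label_added,
            "per_label_removed": self.per_label_removed,
            "segments_removed": self.segments_removed,
            "segments_added": self.segments_added,
        }


def diff(raw: MaskAnnotation, processed: MaskAnnotation) -> AnnotationDiff:
    """Exact before/after comparison of two masks of the same task and shape."""
    if raw.semantics != processed.semantics:
        raise ValueError("cannot diff masks of different semantics")
    if raw.shape != processed.shape:
        raise ValueError(f"shape mismatch: {raw.shape} vs {processed.shape}")
    changed = raw.labels != processed.labels
    rr, cc = np.nonzero(changed)
    old_vals = raw.labels[rr, cc]
    new_vals = processed.labels[rr, cc]
    added: dict[int, int] = {}
    removed: dict[int, int] = {}
    for v in np.unique(new_vals):
        if v > 0:
            added[int(v)] = int((new_vals == v).sum())
    for v in np.unique(old_vals):
        if v > 0:
            removed[int(v)] = int((old_vals == v).sum())
    raw_ids = set(raw.instance_ids())
    new_ids = set(processed.instance_ids())
    patch = [
        (int(r), int(c), int(o), int(n))
        for r, c, o, n in zip(rr, cc, old_vals, new_vals)
    ]
    return AnnotationDiff(
        n_pixels_changed=int(changed.sum()),
        per_label_added=added,
        per_label_removed=removed,
        segments_removed=sorted(raw_ids - new_ids),
        segments_added=sorted(new_ids - raw_ids),
        patch=patch,
    )


def apply_patch(raw: MaskAnnotation, d: AnnotationDiff) -> MaskAnnotation:
    """Replay a diff on the raw mask, reconstructing the processed mask."""
    out = raw.labels.copy()
    for r, c, old, new in d.patch:
        if out[r, c] != old:
            raise ValueError(f"patch mismatch at ({r},{c}): expected {old}, found {out[r, c]}")
        out[r, c] = new
    return MaskAnnotation(out, raw.semantics)


# ---------------------------------------------------------------------------
# Spec-driven pipelines


@dataclass
class PostprocSpec:
    """Ordered post-processing steps, each {'op': ..., **params}."""

    steps: list[dict] = field(default_factory=list)

    VALID_OPS = ("fill_holes", "remove_small", "open", "close")

    def __post_init__(self) -> None:
        for s in self.steps:
            if s.get("op") not in self.VALID_OPS:
                raise ValueError(f"unknown post-processing op {s.get('op')!r}")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PostprocSpec":
        return cls(yaml.safe_load(Path(path).read_text())["steps"])

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump({"steps": self.steps}, sort_keys=False))


def apply_postproc(mask: MaskAnnotation, spec: PostprocSpec) -> tuple[MaskAnnotation, AnnotationDiff]:
    """Apply every step in order; return the result and the raw-vs-final diff."""
    out = mask
    for step in spec.steps:
        op = step["op"]
        if op == "fill_holes":
            out = fill_holes(out)
        elif op == "remove_small":
            out = remove_small(out, step["min_area"])
        else:
            out = morph(out, op, step["radius"])
    return out, diff(mask, out)
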