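"""Initial annotations for the user to correct, instead of drawing from scratch.

Three routes: histogram thresholding (Otsu, constant value, or percentile)
followed by conversion to the project's task kind; copying the previous
image's annotation (sequential data such as time series, where consecutive
frames barely change); and external predictor plugins satisfying
``PredictorContract`` (how pre-trained networks such as Cellpose or a U-Net
plug in — they are not bundled here).

Thresholding assumes bright foreground on dark background (invert for the
opposite); foreground is strictly greater than the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .core import (
    Annotation,
    MaskAnnotation,
    SeedAnnotation,
    TaskKind,
    validate_annotation,
)
from .selection import SelectorKind

logger = logging.getLogger("annotassist")


def _to_gray(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim == 3:
        # ITU-R 601 luminance
        arr = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
    return arr


def otsu_threshold(image: np.ndarray) -> float:
    """Threshold maximizing the between-class variance.

    Candidates are the distinct intensity levels of the image; foreground is
    defined as values strictly greater than the threshold, so the variance
    for candidate t uses the split (x <= t | x > t). Ties go to the smallest
    maximizing level.
    """
    x = _to_gray(image).ravel().astype(np.float64)
    levels, counts = np.unique(x, return_counts=True)
    if levels.size == 1:
        logger.warning("otsu on a constant image: empty foreground")
        return float(levels[0])
    n = x.size
    # cumulative statistics over sorted distinct levels: class 0 = x <= t
    csum = np.cumsum(counts)
    cmean = np.cumsum(counts * levels)
    w0 = csum[:-1] / n                     # candidate t = levels[:-1]
    w1 = 1.0 - w0
    mu0 = cmean[:-1] / csum[:-1]
    mu1 = (cmean[-1] - cmean[:-1]) / (n - csum[:-1])
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(levels[:-1][int(np.argmax(between))])  # argmax takes first max


def threshold(
    image: np.ndarray,
    method: str,
    value: float | None = None,
    q: float | None = None,
    invert: bool = False,
) -> np.ndarray:
    """Binary foreground mask from a histogram threshold.

    ``otsu``: between-class-variance maximizer; ``constant``: the given
    value; ``percentile``: the q-th percentile of the intensities. Foreground
    is strictly above the threshold (strictly below with ``invert``).
    """
    gray = _to_gray(image).astype(np.float64)
    if method == "otsu":
        t = otsu_threshold(gray)
    elif method == "constant":
        if value is None:
            raise ValueError("constant thresholding needs a value")
        t = float(value)
    elif method == "percentile":
        if q is None or not (0 < q < 100):
            raise ValueError("percentile thresholding needs 0 < q < 100")
        t = float(np.percentile(gray, q))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return (gray < t) if invert else (gray > t)


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def label_components(binary: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labeling (8-connectivity default), labels 1..k."""
    labeled, _ = ndimage.label(np.asarray(binary, bool), structure=_STRUCTURES[connectivity])
    return labeled.astype(np.int64)


def binary_to_annotation(
    binary: np.ndarray,
    task: TaskKind,
    fg_class: int = 1,
    connectivity: int = 8,
) -> Annotation:
    """Turn a binary foreground mask into a task-specific annotation.

    semantic: foreground takes the class index; instance: connected
    components labeled 1..k; seed: one point per component at its centroid,
    rounded half-up. Classification has no thresholding interpretation.
    """
    task = TaskKind(task)
    binary = np.asarray(binary, bool)
    if task == TaskKind.classification:
        raise ValueError("thresholding is undefined for classification tasks")
    if task == TaskKind.semantic_segmentation:
        return MaskAnnotation((binary.astype(np.int64) * int(fg_class)), "semantic")
    labeled = label_components(binary, connectivity)
    if task == TaskKind.instance_segmentation:
        return MaskAnnotation(labeled, "instance")
    # seed detection: centroid of each component, rounded half-up
    k = int(labeled.max())
    points = []
    for i in range(1, k + 1):
        r, c = ndimage.center_of_mass(labeled == i)
        points.append((int(np.floor(r + 0.5)), int(np.floor(c + 0.5))))
    return SeedAnnotation(points)


def propagate_previous(
    prev: Annotation | None,
    image_shape: tuple[int, int],
    selector: SelectorKind = SelectorKind.sequential,
) -> Annotation:
    """Copy the previous image's annotation as this image's pre-annotation.

    Only meaningful when images arrive in their natural order, so any
    selector other than sequential is refused.
    """
    if SelectorKind(selector) != SelectorKind.sequential:
        raise ValueError(
            "previous-image propagation requires the sequential selector"
        )
    if prev is None:
        raise ValueError("no previous annotation to propagate")
    if isinstance(prev, MaskAnnotation):
        if prev.shape != tuple(image_shape):
            raise ValueError(
                f"previous mask shape {prev.shape} != image shape {tuple(image_shape)}"
            )
        return prev.copy()
    if isinstance(prev, SeedAnnotation):
        h, w = image_shape
        for r, c in prev.points:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"previous seed ({r},{c}) outside image {h}x{w}")
        return prev.copy()
    return prev  # ClassAnnotation is shape-free; dataclass of immutables


@dataclass
class PredictorContract:
    """External pre-annotation plugin: image -> annotation of the task kind."""

    name: str
    version: str
    task: TaskKind
    predict: Callable[[np.ndarray], Annotation]


def run_predictor(
    image: np.ndarray,
    predictor: PredictorContract,
    task: TaskKind,
    class_names: list[str] | None = None,
) -> tuple[Annotation, dict]:
    """Run a registered predictor and validate its output.

    Returns the annotation and a provenance record naming the predictor.
    """
    if TaskKind(predictor.task) != TaskKind(task):
        raise ValueError(
            f"predictor {predictor.name!r} is registered for {predictor.task}, "
            f"project task is {task}"
        )
    ann = predictor.predict(np.asarray(image))
    violations = validate_annotation(task, ann, np.asarray(image).shape[:2], class_names)
    if violations:
        raise ValueError(
            f"predictor {predictor.name!r} v{predictor.version} produced an "
            f"invalid annotation: {violations}"
        )
    provenance = {"predictor": predictor.name, "version": predictor.version}
    return ann, provenance
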