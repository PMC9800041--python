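"""Rule-based quality control of annotations.

The annotator declares prior knowledge as criteria with bounds — e.g. "one
lesion per image", "segments are at least 50 px", "segments are roughly
convex" — and every submitted annotation is measured against them. A
violated bound raises a warning; the annotator then decides to keep the
annotation or to re-annotate the image. Warnings never block: the human
stays the authority.

Supported measurements (standard region properties): per-image segment count
and mean segment area; per-segment area, eccentricity (of the ellipse with
matching second-order central moments; 0 = circle, towards 1 = line), and
convexity (solidity: area / convex-hull area; 1 for convex shapes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from .core import Annotation, ImageRecord, MaskAnnotation, TaskKind

PER_IMAGE_KINDS = ("segment_count", "mean_segment_area")
PER_SEGMENT_KINDS = ("segment_area", "eccentricity", "convexity")

_FG_STRUCTURE = ndimage.generate_binary_structure(2, 2)


@dataclass
class Criterion:
    """One quality rule: a measurement kind with an inclusive [low, high] band."""

    kind: str
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in PER_IMAGE_KINDS + PER_SEGMENT_KINDS:
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if self.low is None and self.high is None:
            raise ValueError("a criterion needs at least one bound")
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ValueError("low bound exceeds high bound")

    @property
    def scope(self) -> str:
        return "per_image" if self.kind in PER_IMAGE_KINDS else "per_segment"

    def violated_bound(self, value: float) -> str | None:
        """Which bound ``value`` breaks, if any. Bounds are inclusive."""
        if self.low is not None and value < self.low:
            return f"low={self.low}"
        if self.high is not None and value > self.high:
            return f"high={self.high}"
        return None


@dataclass
class SegmentStats:
    segment_id: int
    area: int
    centroid: tuple[float, float]
    eccentricity: float
    convexity: float


@dataclass
class Warning_:
    criterion: Criterion
    measured: float
    violated: str
    subject: str  # segment id as text, or "image"


@dataclass
class InspectionReport:
    warnings: list[Warning_] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "pass" if not self.warnings else "warn"

    def summary(self) -> dict:
        return {
            "verdict": self.verdict,
            "warnings": [
                {
                    "criterion": w.criterion.kind,
                    "measured": w.measured,
                    "violated_bound": w.violated,
                    "subject": w.subject,
                }
                for w in self.warnings
            ],
        }


def region_stats(mask: MaskAnnotation) -> list[SegmentStats]:
    """Per-segment region properties, ordered by segment id.

    Segments are instance ids for instance masks; for semantic masks each
    8-connected component of each class is a segment (ids re-enumerated).
    """
    if mask.semantics == "instance":
        labeled = mask.labels
    else:
        labeled = np.zeros_like(mask.labels)
        next_id = 0
        for lab in sorted(int(v) for v in np.unique(mask.labels) if v > 0):
            comp, k = ndimage.label(mask.labels == lab, structure=_FG_STRUCTURE)
            labeled[comp > 0] = comp[comp > 0] + next_id
            next_id += k
    out = []
    for rp in regionprops(labeled.astype(np.int64)):
        out.append(
            SegmentStats(
                segment_id=int(rp.label),
                area=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                eccentricity=float(rp.eccentricity),
                convexity=float(rp.solidity),
            )
        )
    return sorted(out, key=lambda s: s.segment_id)


def inspect(
    annotation: Annotation,
    criteria: list[Criterion],
    task: TaskKind | None = None,
) -> InspectionReport:
    """Measure an annotation against every criterion; report all violations."""
    if task is not None and TaskKind(task) == TaskKind.classification and criteria:
        raise ValueError("region criteria are incompatible with classification tasks")
    if not isinstance(annotation, MaskAnnotation):
        if criteria:
            raise ValueError(
                f"region criteria need a mask annotation, got {type(annotation).__name__}"
            )
        return InspectionReport()

    stats = region_stats(annotation)
    report = InspectionReport()
    for crit in criteria:
        if crit.scope == "per_image":
            if crit.kind == "segment_count":
                value = float(len(stats))
            else:  # mean_segment_area
                value = float(np.mean([s.area for s in stats])) if stats else 0.0
            bound = crit.violated_bound(value)
            if bound:
                report.warnings.append(Warning_(crit, value, bound, "image"))
        else:
            for s in stats:
                value = {
                    "segment_area": float(s.area),
                    "eccentricity": s.eccentricity,
                    "convexity": s.convexity,
                }[crit.kind]
                bound = crit.violated_bound(value)
                if bound:
                    report.warnings.append(Warning_(crit, value, bound, str(s.segment_id)))
    return report


def resolve(report: InspectionReport, record: ImageRecord, decision: str = "keep") -> ImageRecord:
    """Apply the annotator's verdict on a warned annotation.

    keep: the annotation stands (warnings stay logged); reannotate: the image
    returns to the unannotated pool. A passing report auto-accepts.
    """
    if report.verdict == "pass" or decision == "keep":
        record.annotated = True
    elif decision == "reannotate":
        record.annotated = False
    else:
        raise ValueError(f"unknown decision {decision!r}")
    return record


def check_inspector_independence(
    inspector_name: str, inspector_version: str,
    preannotator_name: str | None, preannotator_version: str | None,
) -> None:
    """Refuse a model-based inspector identical to the active pre-annotator.

    Inspecting an annotation with the same model that proposed it forms a
    short circuit and validates nothing.
    """
    if inspector_name == preannotator_name and inspector_version == preannotator_version:
        raise ValueError(
            f"inspector {inspector_name!r} v{inspector_version} is the active "
            "pre-annotator; using the same model for both is a short circuit"
        )
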