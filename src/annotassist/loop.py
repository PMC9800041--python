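"""The headless annotation loop: select -> preprocess -> pre-annotate ->
[external edit] -> post-process -> inspect -> persist.

Each module can be switched off in ``LoopConfig``; a disabled module is an
identity pass-through. The loop is deterministic given the configuration and
seed. "External edit" is the caller's job: ``next_item`` hands out an image
id with its pre-annotation and the caller submits a (corrected) annotation
via ``submit``. An image whose inspection the annotator rejects re-enters
the queue at its head.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from . import preannotation, selection
from .core import (
    Annotation,
    ClassAnnotation,
    MaskAnnotation,
    Project,
    SeedAnnotation,
    TaskKind,
    read_image,
    validate_annotation,
    write_labels,
    write_mask,
    write_seeds,
)
from .inspection import Criterion, InspectionReport, inspect, resolve
from .postannotation import AnnotationDiff, PostprocSpec, apply_postproc
from .preprocessing import PreprocSpec, apply_pipeline
from .selection import SelectorKind


@dataclass
class LoopConfig:
    """Per-module switches and settings for one annotation session."""

    selector: SelectorKind | None = SelectorKind.sequential
    seed: int = 0
    picked_ids: list[str] = field(default_factory=list)
    metric: str = "l2"
    preproc: PreprocSpec | None = None
    preannotate_method: str | None = None  # otsu | constant | percentile | previous
    preannotate_value: float | None = None
    preannotate_q: float | None = None
    invert: bool = False
    postproc: PostprocSpec | None = None
    criteria: list[Criterion] = field(default_factory=list)


@dataclass
class NextItem:
    image_id: str
    image: np.ndarray
    preannotation: Annotation | None
    done: bool = False


class AnnotationLoop:
    """Drives one project through the assisted-annotation cycle."""

    def __init__(self, project: Project, config: LoopConfig,
                 log_path: Union[str, Path, None] = None):
        self.project = project
        self.config = config
        self.log_path = Path(log_path) if log_path else None
        self.issued: set[str] = set()
        self.requeued: list[str] = []  # rejected images jump the queue
        self.last_annotation: Annotation | None = None
        self.last_reports: dict[str, InspectionReport] = {}

    # -- event log ---------------------------------------------------------

    def _log(self, event: str, **payload) -> None:
        if self.log_path is None:
            return
        with open(self.log_path, "a") as f:
            f.write(json.dumps({"ts": time.time(), "event": event, **payload}) + "\n")

    # -- ordering ----------------------------------------------------------

    def _order(self) -> list[str]:
        records = self.project.records
        kind = self.config.selector
        if kind is None or kind == SelectorKind.sequential:
            order = selection.sequential_order(records)
        elif kind == SelectorKind.random:
            order = selection.random_order(records, self.config.seed)
        elif kind == SelectorKind.cherry:
            order = selection.cherry_order(records, self.config.picked_ids)
        elif kind == SelectorKind.heterogeneity:
            images = {r.id: read_image(self.project.image_dir / r.filename)
                      for r in records if not r.annotated}
            unann = [r for r in records if not r.annotated]
            if len(unann) < 2:
                order = selection.sequential_order(records)
            else:
                order, _ = selection.order_by_heterogeneity(
                    unann, images, metric=self.config.metric)
        else:
            raise ValueError(f"unknown selector {kind}")
        head = [i for i in self.requeued if i in order]
        return head + [i for i in order if i not in head]

    # -- next --------------------------------------------------------------

    def next_item(self) -> NextItem:
        """The next image to annotate, with its pre-annotation (if enabled)."""
        order = self._order()
        if not order:
            return NextItem("", np.empty(0), None, done=True)
        image_id = order[0]
        record = self.project.record(image_id)
        image = read_image(self.project.image_dir / record.filename)

        if self.config.preproc is not None:
            image = apply_pipeline(image, self.config.preproc, image_id)

        pre: Annotation | None = None
        method = self.config.preannotate_method
        if method in ("otsu", "constant", "percentile"):
            binary = preannotation.threshold(
                image, method, value=self.config.preannotate_value,
                q=self.config.preannotate_q, invert=self.config.invert)
            pre = preannotation.binary_to_annotation(binary, self.project.meta.task)
        elif method == "previous":
            pre = preannotation.propagate_previous(
                self.last_annotation, image.shape[:2],
                self.config.selector or SelectorKind.sequential)

        self.issued.add(image_id)
        self._log("next", image_id=image_id, preannotation=method)
        return NextItem(image_id, image, pre)

    # -- submit ------------------------------------------------------------

    def submit(
        self, image_id: str, annotation: Annotation, decision: str = "keep"
    ) -> tuple[str, InspectionReport | None, AnnotationDiff | None]:
        """Validate, post-process, inspect, and persist an annotation.

        Returns (status, report, diff): status is ``accepted``, ``warned``
        (criteria violated; the given decision was applied), or ``rejected``
        (validation failed; nothing persisted).
        """
        if image_id not in self.issued:
            raise ValueError(f"image {image_id!r} was not issued by next_item")
        record = self.project.record(image_id)
        meta = self.project.meta

        violations = validate_annotation(
            meta.task, annotation, (record.height, record.width), meta.class_names)
        if violations:
            self._log("rejected", image_id=image_id, violations=violations)
            return "rejected", None, None

        d: AnnotationDiff | None = None
        if self.config.postproc is not None and isinstance(annotation, MaskAnnotation):
            annotation, d = apply_postproc(annotation, self.config.postproc)

        report: InspectionReport | None = None
        if self.config.criteria and isinstance(annotation, MaskAnnotation):
            report = inspect(annotation, self.config.criteria, meta.task)

        if report is not None and report.verdict == "warn":
            resolve(report, record, decision)
            self.last_reports[image_id] = report
            if decision == "reannotate":
                self.requeued.insert(0, image_id)
                self.issued.discard(image_id)
                self._log("reannotate", image_id=image_id,
                          warnings=len(report.warnings))
                self.project.save()
                return "warned", report, d
            status = "warned"
        else:
            record.annotated = True
            status = "accepted"

        if image_id in self.requeued:
            self.requeued.remove(image_id)
        self._persist(image_id, annotation)
        self.last_annotation = annotation
        self.project.save()
        self._log(status, image_id=image_id)
        return status, report, d

    def _persist(self, image_id: str, annotation: Annotation) -> None:
        ann_dir = self.project.annotation_dir
        ann_dir.mkdir(parents=True, exist_ok=True)
        if isinstance(annotation, MaskAnnotation):
            write_mask(annotation, ann_dir / f"{image_id}.png")
        elif isinstance(annotation, ClassAnnotation):
            path = ann_dir / "labels.json"
            existing = json.loads(path.read_text()) if path.exists() else {}
            existing[image_id] = annotation.distribution
            path.write_text(json.dumps(existing, indent=1, sort_keys=True))
        elif isinstance(annotation, SeedAnnotation):
            path = ann_dir / "seeds.csv"
            from .core import read_seeds

            existing_seeds = read_seeds(path) if path.exists() else {}
            existing_seeds[image_id] = annotation
            write_seeds(existing_seeds, path)

    @property
    def remaining(self) -> int:
        return sum(1 for r in self.project.records if not r.annotated)
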