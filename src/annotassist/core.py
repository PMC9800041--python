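"""Project metadata, the task-adaptive annotation data model, and on-disk formats.

An annotation project declares exactly one task kind. The annotation payload
adapts to it: a fuzzy class distribution for classification, a label image for
semantic or instance segmentation, a point list for seed detection. Masks are
stored as single-channel 16-bit PNG (TIFF fallback for larger label ranges),
class labels as CSV/JSON tables, seeds as CSV point tables.

Conventions used throughout the package: pixel coordinates are (row, col),
0-based; regions are half-open ``[r0, r1) x [c0, c1)``; background is label 0
in both semantic and instance masks.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("annotassist")

SUPPORTED_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

LABEL_SUM_TOL = 1e-6


class TaskKind(str, enum.Enum):
    """The four supported annotation task kinds."""

    classification = "classification"
    semantic_segmentation = "semantic_segmentation"
    instance_segmentation = "instance_segmentation"
    seed_detection = "seed_detection"


@dataclass
class ProjectMeta:
    """Meta-information a project is created with.

    ``class_names`` holds the annotatable classes: at least one for
    classification/semantic tasks, a single foreground class for instance
    segmentation and seed detection.
    """

    name: str
    task: TaskKind
    class_names: list[str]
    image_dir: str
    annotation_dir: str
    module_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.task = TaskKind(self.task)
        if len(self.class_names) != len(set(self.class_names)):
            raise ValueError("class_names must be unique")
        if not self.class_names:
            raise ValueError("at least one class name is required")
        if Path(self.image_dir) == Path(self.annotation_dir):
            raise ValueError("image_dir and annotation_dir must be distinct")
        if self.task in (TaskKind.instance_segmentation, TaskKind.seed_detection):
            if len(self.class_names) != 1:
                raise ValueError(
                    f"{self.task.value} allows exactly one foreground class"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["task"] = self.task.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectMeta":
        return cls(**d)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ProjectMeta":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ImageRecord:
    """Index entry for one image in the project."""

    id: str
    filename: str
    height: int
    width: int
    channels: int
    content_hash: str
    annotated: bool = False


@dataclass
class ClassAnnotation:
    """Fuzzy class label: a distribution over class names summing to 1."""

    distribution: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.distribution.values())
        if abs(total - 1.0) > LABEL_SUM_TOL:
            raise ValueError(f"class weights sum to {total}, expected 1")
        for name, w in self.distribution.items():
            if not (0.0 <= w <= 1.0 + 1e-12):
                raise ValueError(f"weight for {name!r} outside [0,1]: {w}")

    @property
    def is_crisp(self) -> bool:
        return any(abs(w - 1.0) <= 1e-9 for w in self.distribution.values())

    @property
    def top_class(self) -> str:
        return max(self.distribution, key=self.distribution.get)


@dataclass
class MaskAnnotation:
    """Label image: semantic (value = class index, 0 background) or
    instance (value = positive instance id, 0 background)."""

    labels: np.ndarray
    semantics: str = "semantic"  # or "instance"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask must be integer-typed")
        if self.labels.min(initial=0) < 0:
            raise ValueError("mask values must be >= 0")
        if self.semantics not in ("semantic", "instance"):
            raise ValueError("semantics must be 'semantic' or 'instance'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def instance_ids(self) -> list[int]:
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v > 0]

    def copy(self) -> "MaskAnnotation":
        return MaskAnnotation(self.labels.copy(), self.semantics)


@dataclass
class SeedAnnotation:
    """Point annotations for counting objects: (row, col) per instance."""

    points: list[tuple[int, int]]
    classes: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = [(int(r), int(c)) for r, c in self.points]
        if self.classes is not None and len(self.classes) != len(self.points):
            raise ValueError("classes must match points in length")

    def copy(self) -> "SeedAnnotation":
        return SeedAnnotation(list(self.points), list(self.classes) if self.classes else None)


Annotation = Union[ClassAnnotation, MaskAnnotation, SeedAnnotation]


def content_hash(path: Union[str, Path]) -> str:
    """SHA-256 over the raw file bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Read a 2-D grayscale or RGB image as a numpy array."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr


def _image_shape_channels(arr: np.ndarray) -> tuple[int, int, int]:
    if arr.ndim == 2:
        return arr.shape[0], arr.shape[1], 1
    if arr.ndim == 3 and arr.shape[2] in (1, 3):
        return arr.shape[0], arr.shape[1], arr.shape[2]
    raise ValueError(f"unsupported image shape {arr.shape}")


def index_images(image_dir: Union[str, Path]) -> list[ImageRecord]:
    """Build the image index: one record per readable supported file.

    Unreadable files are skipped with a logged warning. Two files with the
    same stem (differing only in extension) are an indexing error because the
    stem is the image id.
    """
    image_dir = Path(image_dir)
    records: list[ImageRecord] = []
    seen: dict[str, str] = {}
    for p in sorted(image_dir.iterdir()):
        if not p.is_file() or p.suffix.lower() not in SUPPORTED_EXTENSIONS:
            continue
        if p.stem in seen:
            raise ValueError(
                f"image id collision: {seen[p.stem]!r} and {p.name!r} share stem {p.stem!r}"
            )
        try:
            arr = read_image(p)
            h, w, c = _image_shape_channels(arr)
        except Exception as exc:  # unreadable or unsupported content
            logger.warning("skipping unreadable image %s: %s", p.name, exc)
            continue
        seen[p.stem] = p.name
        records.append(
            ImageRecord(
                id=p.stem,
                filename=p.name,
                height=h,
                width=w,
                channels=c,
                content_hash=content_hash(p),
            )
        )
    return records


class Project:
    """A persisted annotation project: meta config + image index on disk."""

    CONFIG_NAME = "project.yaml"
    INDEX_NAME = "index.json"

    def __init__(self, root: Path, meta: ProjectMeta, records: list[ImageRecord]):
        self.root = Path(root)
        self.meta = meta
        self.records = records

    @property
    def image_dir(self) -> Path:
        return self.root / self.meta.image_dir

    @property
    def annotation_dir(self) -> Path:
        return self.root / self.meta.annotation_dir

    def record(self, image_id: str) -> ImageRecord:
        for r in self.records:
            if r.id == image_id:
                return r
        raise KeyError(f"unknown image id {image_id!r}")

    def save(self) -> None:
        self.meta.save(self.root / self.CONFIG_NAME)
        payload = [dataclasses.asdict(r) for r in self.records]
        (self.root / self.INDEX_NAME).write_text(json.dumps(payload, indent=1))

    @classmethod
    def open(cls, root: Union[str, Path]) -> "Project":
        root = Path(root)
        meta = ProjectMeta.load(root / cls.CONFIG_NAME)
        payload = json.loads((root / cls.INDEX_NAME).read_text())
        records = [ImageRecord(**r) for r in payload]
        return cls(root, meta, records)


def create_project(root: Union[str, Path], meta: ProjectMeta) -> Project:
    """Create (or idempotently reload) a project at ``root``.

    The image directory must already contain at least one readable image.
    Re-running on an unchanged directory reproduces the same index.
    """
    root = Path(root)
    config_path = root / Project.CONFIG_NAME
    if config_path.exists():
        existing = Project.open(root)
        if existing.meta.to_dict() != meta.to_dict():
            raise ValueError("project already exists with different meta")
        fresh = index_images(root / meta.image_dir)
        by_id = {r.id: r for r in existing.records}
        for r in fresh:  # keep annotation status for unchanged images
            if r.id in by_id and by_id[r.id].content_hash == r.content_hash:
                r.annotated = by_id[r.id].annotated
        existing.records = fresh
        existing.save()
        return existing

    image_dir = root / meta.image_dir
    if not image_dir.is_dir():
        raise FileNotFoundError(f"image directory {image_dir} does not exist")
    records = index_images(image_dir)
    if not records:
        raise ValueError(f"no readable images found in {image_dir}")
    (root / meta.annotation_dir).mkdir(parents=True, exist_ok=True)
    project = Project(root, meta, records)
    project.save()
    return project


# ---------------------------------------------------------------------------
# Mask I/O


def write_mask(mask: MaskAnnotation, path: Union[str, Path]) -> None:
    """Write a label mask: 16-bit single-channel PNG, or TIFF for any depth.

    PNG cannot hold labels above 65535; such masks must go to TIFF.
    """
    path = Path(path)
    labels = mask.labels
    maxv = int(labels.max(initial=0))
    if path.suffix.lower() == ".png":
        if maxv > 65535:
            raise ValueError(
                f"label {maxv} exceeds the 16-bit PNG range; write a .tif instead"
            )
        iio.imwrite(path, labels.astype(np.uint16))
    elif path.suffix.lower() in (".tif", ".tiff"):
        dtype = np.uint16 if maxv <= 65535 else np.uint32
        tifffile.imwrite(path, labels.astype(dtype))
    else:
        raise ValueError(f"unsupported mask format {path.suffix!r}")


def read_mask(path: Union[str, Path], semantics: str = "semantic") -> MaskAnnotation:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return MaskAnnotation(np.asarray(arr).astype(np.int64), semantics)


# ---------------------------------------------------------------------------
# Class-label tables (CSV / JSON)


def write_labels(
    labels: dict[str, ClassAnnotation], path: Union[str, Path], class_names: list[str]
) -> None:
    """Write fuzzy class labels as CSV (image_id, one column per class) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {iid: ann.distribution for iid, ann in labels.items()}
        path.write_text(json.dumps(payload, indent=1))
        return
    rows = []
    for iid, ann in labels.items():
        row: dict[str, object] = {"image_id": iid}
        for cname in class_names:
            row[cname] = repr(float(ann.distribution.get(cname, 0.0)))
        rows.append(row)
    pd.DataFrame(rows, columns=["image_id", *class_names]).to_csv(path, index=False)


def read_labels(path: Union[str, Path]) -> dict[str, ClassAnnotation]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return {iid: ClassAnnotation(dist) for iid, dist in payload.items()}
    df = pd.read_csv(path, dtype={"image_id": str})
    class_cols = [c for c in df.columns if c != "image_id"]
    out: dict[str, ClassAnnotation] = {}
    for _, row in df.iterrows():
        dist = {c: float(row[c]) for c in class_cols}
        total = sum(dist.values())
        if abs(total - 1.0) > LABEL_SUM_TOL:
            raise ValueError(
                f"row for image {row['image_id']!r}: weights sum to {total}, expected 1"
            )
        out[str(row["image_id"])] = ClassAnnotation(dist)
    return out


# ---------------------------------------------------------------------------
# Seed tables (CSV: image_id,row,col[,class])


def write_seeds(seeds: dict[str, SeedAnnotation], path: Union[str, Path]) -> None:
    rows = []
    any_class = any(s.classes is not None for s in seeds.values())
    for iid, ann in seeds.items():
        classes = ann.classes or [None] * len(ann.points)
        for (r, c), cls in zip(ann.points, classes):
            row: dict[str, object] = {"image_id": iid, "row": r, "col": c}
            if any_class:
                row["class"] = cls
            rows.append(row)
    cols = ["image_id", "row", "col"] + (["class"] if any_class else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_seeds(path: Union[str, Path]) -> dict[str, SeedAnnotation]:
    df = pd.read_csv(path, dtype={"image_id": str})
    has_class = "class" in df.columns
    out: dict[str, SeedAnnotation] = {}
    for iid, group in df.groupby("image_id", sort=False):
        points = [(int(r), int(c)) for r, c in zip(group["row"], group["col"])]
        classes = [str(c) for c in group["class"]] if has_class else None
        out[str(iid)] = SeedAnnotation(points, classes)
    return out


# ---------------------------------------------------------------------------
# Validation


def validate_annotation(
    task: TaskKind,
    ann: Annotation,
    image_shape: tuple[int, int],
    class_names: list[str] | None = None,
) -> list[str]:
    """Check an annotation against its task; return every violation found.

    Violations are data, not exceptions: an empty list means the annotation
    is acceptable.
    """
    task = TaskKind(task)
    violations: list[str] = []

    if task == TaskKind.classification:
        if not isinstance(ann, ClassAnnotation):
            return [f"classification expects ClassAnnotation, got {type(ann).__name__}"]
        if class_names is not None:
            for name in ann.distribution:
                if name not in class_names:
                    violations.append(f"unknown class {name!r}")
        return violations

    if task in (TaskKind.semantic_segmentation, TaskKind.instance_segmentation):
        if not isinstance(ann, MaskAnnotation):
            return [f"{task.value} expects MaskAnnotation, got {type(ann).__name__}"]
        if ann.shape != tuple(image_shape):
            violations.append(
                f"mask shape {ann.shape} does not match image shape {tuple(image_shape)}"
            )
        if task == TaskKind.semantic_segmentation and class_names is not None:
            # semantic label values are class indices < n_classes, 0 = background
            bad = np.unique(ann.labels[ann.labels >= len(class_names)])
            for v in bad:
                violations.append(
                    f"semantic label {int(v)} out of range for {len(class_names)} classes"
                )
        return violations

    if task == TaskKind.seed_detection:
        if not isinstance(ann, SeedAnnotation):
            return [f"seed_detection expects SeedAnnotation, got {type(ann).__name__}"]
        h, w = image_shape
        for r, c in ann.points:
            if not (0 <= r < h and 0 <= c < w):
                violations.append(f"seed ({r}, {c}) outside image bounds {h}x{w}")
        return violations

    raise AssertionError(f"unhandled task {task}")
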