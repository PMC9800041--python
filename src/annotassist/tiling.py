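"""Deterministic tiling of large images into overlapping fragments.

Annotating a 10k x 10k micrograph with hundreds of objects is unwieldy;
fragments are easier to annotate and cheaper to train on. Tiles of size
``th x tw`` are placed at stride ``tile - overlap``; the final row/column of
tiles is shifted inward so every tile is full-size, lies entirely inside the
image, and the union covers every pixel (no padding). Fragment names encode
the tile origin, making the local-to-global coordinate mapping invertible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .core import MaskAnnotation, SeedAnnotation
from .preprocessing import crop, crop_mask, crop_seeds

Region = tuple[int, int, int, int]


def _starts(extent: int, tile: int, overlap: int) -> list[int]:
    stride = tile - overlap
    starts = list(range(0, extent - tile + 1, stride))
    if starts[-1] != extent - tile:  # shift the last tile inward to the border
        starts.append(extent - tile)
    return starts


@dataclass
class TileGrid:
    height: int
    width: int
    tile_h: int
    tile_w: int
    overlap: int
    regions: list[tuple[str, Region]] = field(default_factory=list)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps({
            "height": self.height, "width": self.width,
            "tile_h": self.tile_h, "tile_w": self.tile_w,
            "overlap": self.overlap,
            "regions": [[tid, list(reg)] for tid, reg in self.regions],
        }))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TileGrid":
        d = json.loads(Path(path).read_text())
        return cls(d["height"], d["width"], d["tile_h"], d["tile_w"], d["overlap"],
                   [(tid, tuple(reg)) for tid, reg in d["regions"]])

    def origin(self, tile_id: str) -> tuple[int, int]:
        for tid, (r0, c0, _, _) in self.regions:
            if tid == tile_id:
                return r0, c0
        raise KeyError(f"unknown tile {tile_id!r}")


def tile_id(r0: int, c0: int) -> str:
    return f"r{r0}_c{c0}"


def grid_tiles(h: int, w: int, th: int, tw: int, overlap: int = 0) -> TileGrid:
    """Tile positions covering an h x w image with th x tw tiles."""
    if not (1 <= th <= h and 1 <= tw <= w):
        raise ValueError(f"tile {th}x{tw} does not fit image {h}x{w}")
    if not (0 <= overlap < min(th, tw)):
        raise ValueError(f"overlap {overlap} must be < tile size {min(th, tw)}")
    regions = [
        (tile_id(r0, c0), (r0, c0, r0 + th, c0 + tw))
        for r0 in _starts(h, th, overlap)
        for c0 in _starts(w, tw, overlap)
    ]
    return TileGrid(h, w, th, tw, overlap, regions)


def cut(
    grid: TileGrid,
    image: np.ndarray | None = None,
    mask: MaskAnnotation | None = None,
    seeds: SeedAnnotation | None = None,
    image_id: str = "img",
) -> dict[str, dict]:
    """Cut image / mask / seeds into named fragments.

    Fragment names are ``{image_id}__{tile_id}``. Masks keep their label
    values; seeds are duplicated into every tile containing them, with
    tile-local coordinates.
    """
    shapes = [x.shape[:2] if not isinstance(x, MaskAnnotation) else x.shape
              for x in (image, mask) if x is not None]
    for s in shapes:
        if (s[0], s[1]) != (grid.height, grid.width):
            raise ValueError(f"input shape {s} does not match grid "
                             f"{grid.height}x{grid.width}")
    out: dict[str, dict] = {}
    for tid, region in grid.regions:
        frag: dict = {"region": region}
        if image is not None:
            frag["image"] = crop(image, region)
        if mask is not None:
            frag["mask"] = crop_mask(mask, region)
        if seeds is not None:
            frag["seeds"] = crop_seeds(seeds, region)
        out[f"{image_id}__{tid}"] = frag
    return out


def to_global(grid: TileGrid, tile_id_: str, local_point: tuple[int, int]) -> tuple[int, int]:
    """Map a tile-local (row, col) back to source-image coordinates."""
    r0, c0 = grid.origin(tile_id_)
    r, c = local_point
    if not (0 <= r < grid.tile_h and 0 <= c < grid.tile_w):
        raise ValueError(f"point {local_point} outside tile {grid.tile_h}x{grid.tile_w}")
    return r + r0, c + c0


def to_local(grid: TileGrid, tile_id_: str, global_point: tuple[int, int]) -> tuple[int, int]:
    """Map a source-image (row, col) into a tile's frame; error if outside."""
    r0, c0 = grid.origin(tile_id_)
    r, c = global_point[0] - r0, global_point[1] - c0
    if not (0 <= r < grid.tile_h and 0 <= c < grid.tile_w):
        raise ValueError(f"point {global_point} not inside tile {tile_id_!r}")
    return r, c


def stitch(grid: TileGrid, fragments: dict[str, np.ndarray]) -> np.ndarray:
    """Reassemble fragments into the source frame (overlaps overwrite equal pixels)."""
    sample = next(iter(fragments.values()))
    out = np.zeros((grid.height, grid.width) + sample.shape[2:], dtype=sample.dtype)
    for tid, (r0, c0, r1, c1) in grid.regions:
        key = next(k for k in fragments if k == tid or k.endswith("__" + tid))
        out[r0:r1, c0:c1] = fragments[key]
    return out
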