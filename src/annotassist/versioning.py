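"""Dataset version control via content-addressed manifests.

Annotation datasets evolve — policies change, errors are corrected, new
samples arrive — so every state worth keeping is committed as a manifest
(relative path -> SHA-256, size) whose file contents go into a deduplicated
blob store under ``.annotassist/store/``. Commits chain through parent ids in
an append-only JSONL log, giving history, diffs between any two versions,
and exact byte-level rollback. Before a checkout overwrites the working
tree, the current state is auto-committed as a safety snapshot.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .core import content_hash

META_DIR = ".annotassist"


@dataclass
class Manifest:
    """Snapshot of the dataset: normalized relative path -> (hash, size)."""

    entries: dict[str, tuple[str, int]] = field(default_factory=dict)
    timestamp: float = 0.0

    def to_dict(self) -> dict:
        return {
            "entries": {p: [h, s] for p, (h, s) in sorted(self.entries.items())},
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Manifest":
        return cls({p: (h, s) for p, (h, s) in d["entries"].items()}, d["timestamp"])

    def equals(self, other: "Manifest") -> bool:
        """Content equality: same paths mapping to the same hashes."""
        mine = {p: h for p, (h, _) in self.entries.items()}
        theirs = {p: h for p, (h, _) in other.entries.items()}
        return mine == theirs


@dataclass
class Commit:
    id: str
    parent: str | None
    message: str
    timestamp: float
    manifest: Manifest

    @staticmethod
    def compute_id(manifest: Manifest, parent: str | None, message: str, timestamp: float) -> str:
        payload = json.dumps(
            {
                "entries": {p: h for p, (h, _) in sorted(manifest.entries.items())},
                "parent": parent,
                "message": message,
                "timestamp": timestamp,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def snapshot(dataset_dir: Union[str, Path]) -> Manifest:
    """Hash every data file under the dataset directory.

    Covers all regular files (images/, annotations/, configs) except the
    version-control metadata itself. Deterministic path ordering.
    """
    root = Path(dataset_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory {root} does not exist")
    entries: dict[str, tuple[str, int]] = {}
    for p in sorted(root.rglob("*")):
        if not p.is_file():
            continue
        rel = p.relative_to(root).as_posix()
        if rel.split("/", 1)[0] == META_DIR:
            continue
        try:
            entries[rel] = (content_hash(p), p.stat().st_size)
        except OSError as exc:
            raise OSError(f"unreadable file {rel!r}: {exc}") from exc
    return Manifest(entries, timestamp=time.time())


class Repository:
    """Commit log plus blob store for one dataset directory."""

    def __init__(self, dataset_dir: Union[str, Path]):
        self.root = Path(dataset_dir)
        self.meta = self.root / META_DIR
        self.store = self.meta / "store"
        self.log_path = self.meta / "log.jsonl"
        self.store.mkdir(parents=True, exist_ok=True)

    # -- log ---------------------------------------------------------------

    def log(self) -> list[Commit]:
        if not self.log_path.exists():
            return []
        commits = []
        for line in self.log_path.read_text().splitlines():
            d = json.loads(line)
            commits.append(
                Commit(d["id"], d["parent"], d["message"], d["timestamp"],
                       Manifest.from_dict(d["manifest"]))
            )
        return commits

    def head(self) -> Commit | None:
        log = self.log()
        return log[-1] if log else None

    def get_commit(self, commit_id: str) -> Commit:
        for c in self.log():
            if c.id == commit_id or c.id.startswith(commit_id):
                return c
        raise KeyError(f"unknown commit {commit_id!r}")

    # -- commit ------------------------------------------------------------

    def _blob_path(self, digest: str) -> Path:
        return self.store / digest[:2] / digest[2:]

    def n_blobs(self) -> int:
        return sum(1 for p in self.store.rglob("*") if p.is_file())

    def commit(self, message: str, manifest: Manifest | None = None) -> Commit:
        """Snapshot (unless given) and record a commit; blobs are deduplicated."""
        if manifest is None:
            manifest = snapshot(self.root)
        for rel, (digest, _) in manifest.entries.items():
            blob = self._blob_path(digest)
            if not blob.exists():
                blob.parent.mkdir(parents=True, exist_ok=True)
                shutil.copyfile(self.root / rel, blob)
        parent = self.head()
        ts = time.time()
        cid = Commit.compute_id(manifest, parent.id if parent else None, message, ts)
        c = Commit(cid, parent.id if parent else None, message, ts, manifest)
        with open(self.log_path, "a") as f:
            f.write(json.dumps({
                "id": c.id, "parent": c.parent, "message": c.message,
                "timestamp": c.timestamp, "manifest": c.manifest.to_dict(),
            }) + "\n")
        return c

    # -- diff --------------------------------------------------------------

    def diff(self, commit_a: str, commit_b: str) -> dict[str, list[str]]:
        """Paths added, removed, and modified going from commit a to commit b."""
        ma = self.get_commit(commit_a).manifest
        mb = self.get_commit(commit_b).manifest
        pa, pb = set(ma.entries), set(mb.entries)
        return {
            "added": sorted(pb - pa),
            "removed": sorted(pa - pb),
            "modified": sorted(
                p for p in pa & pb if ma.entries[p][0] != mb.entries[p][0]
            ),
        }

    # -- checkout ----------------------------------------------------------

    def checkout(self, commit_id: str) -> Commit:
        """Restore the working tree to a committed state, byte-identical.

        The current uncommitted state is auto-committed first so nothing is
        silently lost. Blob integrity is verified before any file is written.
        """
        target = self.get_commit(commit_id)
        for rel, (digest, _) in target.manifest.entries.items():
            blob = self._blob_path(digest)
            if not blob.exists():
                raise RuntimeError(f"integrity error: missing blob for {rel!r}")
            if content_hash(blob) != digest:
                raise RuntimeError(f"integrity error: corrupted blob for {rel!r}")

        self.commit(f"auto-save before checkout of {target.id[:12]}")

        current = snapshot(self.root)
        for rel in set(current.entries) - set(target.manifest.entries):
            (self.root / rel).unlink()
        for rel, (digest, _) in target.manifest.entries.items():
            dest = self.root / rel
            if rel in current.entries and current.entries[rel][0] == digest:
                continue
            dest.parent.mkdir(parents=True, exist_ok=True)
            shutil.copyfile(self._blob_path(digest), dest)

        restored = snapshot(self.root)
        if not restored.equals(target.manifest):
            raise RuntimeError("checkout verification failed: tree does not match commit")
        return target
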