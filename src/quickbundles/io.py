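"""Streamline file formats and report serialization.

Two interchange formats are supported:

* **TrackVis ``.trk``** (version 2, 1000-byte header), through nibabel.
  Points are kept in world millimeter coordinates: the file's
  voxel-to-world transform is applied on read and the identity transform
  is recorded on write, so in-memory coordinates are always mm.
* a **plain-text polyline format**, one streamline per line:
  ``id k x1 y1 z1 ... xk yk zk`` with 1-based ids; lossless for double
  precision and convenient for fixtures and diffing.

Cluster assignments are written as a two-column ``streamline_id
cluster_id`` table (both 1-based); metric reports as flat ``key=value``
text or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.streamlines.tractogram import Tractogram

from .cluster import ClusterMap
from .streamlines import Tractography

__all__ = [
    "read_trk",
    "write_trk",
    "read_text",
    "write_text",
    "write_labels",
    "read_labels",
    "write_report",
]


def read_trk(path: str | Path) -> Tractography:
    """Load a TrackVis .trk file; returned points are world mm."""
    path = Path(path)
    try:
        obj = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises several header/IO error types
        raise IOError(f"cannot read {path} as a .trk file: {exc}") from exc
    streamlines = [np.asarray(s, dtype=np.float64) for s in obj.streamlines]
    return Tractography(streamlines)


def write_trk(t: Tractography, path: str | Path) -> None:
    """Write streamlines to TrackVis .trk (v2); coordinates stored as mm
    world with an identity voxel-to-world transform."""
    tractogram = Tractogram(t.streamlines, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(Path(path)))


def write_text(t: Tractography, path: str | Path) -> None:
    """Write the plain-text polyline format: ``id k x1 y1 z1 ...``."""
    with open(path, "w") as fh:
        for sid, s in t.items():
            coords = " ".join(repr(float(v)) for v in s.ravel())
            fh.write(f"{sid} {s.shape[0]} {coords}\n")


def read_text(path: str | Path) -> Tractography:
    """Read the plain-text polyline format; raises with the offending line
    number on malformed input."""
    streamlines = []
    ids = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            try:
                sid = int(fields[0])
                k = int(fields[1])
                if k < 2:
                    raise ValueError(f"k={k} < 2")
                values = [float(v) for v in fields[2:]]
                if len(values) != 3 * k:
                    raise ValueError(f"expected {3 * k} coordinates, got {len(values)}")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed polyline line: {exc}") from exc
            streamlines.append(np.array(values).reshape(k, 3))
            ids.append(sid)
    return Tractography(streamlines, ids=np.array(ids, dtype=np.int64))


def write_labels(cm: ClusterMap, path: str | Path) -> None:
    """Write cluster assignments as ``streamline_id cluster_id`` (1-based)."""
    labels = cm.labels()
    with open(path, "w") as fh:
        fh.write("# streamline_id cluster_id\n")
        for sid in sorted(labels):
            fh.write(f"{sid} {labels[sid]}\n")


def read_labels(path: str | Path) -> dict[int, int]:
    """Read a two-column assignment table back into an id -> cluster map."""
    out: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, cid = line.split()
            out[int(sid)] = int(cid)
    return out


def write_report(report: dict, path: str | Path, fmt: str = "json") -> None:
    """Serialize a flat metrics report as JSON or ``key=value`` text."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    elif fmt == "text":
        lines = [f"{k}={report[k]}" for k in sorted(report)]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"fmt must be 'json' or 'text', got {fmt!r}")
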