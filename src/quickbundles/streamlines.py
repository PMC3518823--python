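"""Streamline and tractography primitives.

A *streamline* is an ordered polyline of K >= 2 points in 3-D millimeter
coordinates, represented as a ``(K, 3)`` float64 :class:`numpy.ndarray`.
Streamlines are directionless objects: a streamline and its point-reversed
("flipped") version describe the same curve.

A *tractography* is an ordered list of streamlines with stable 1-based
integer ids.  The order defines the processing order of the online
clustering algorithm; the ids survive filtering and permutation so that
cluster memberships can always be traced back to the original data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "InvalidStreamlineError",
    "Streamline",
    "Tractography",
    "as_streamline",
    "arc_length",
    "resample",
    "flip",
]


class InvalidStreamlineError(ValueError):
    """Raised when a polyline cannot be treated as a streamline."""


#: Type alias documenting the in-memory streamline representation.
Streamline = np.ndarray


def as_streamline(points: Sequence | np.ndarray) -> Streamline:
    """Coerce *points* to a ``(K, 3)`` float64 array and validate it.

    Raises
    ------
    InvalidStreamlineError
        If the input has fewer than 2 points, is not 3-D, or contains
        non-finite coordinates.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidStreamlineError(
            f"streamline must be an (K, 3) array of 3-D points, got shape {pts.shape}"
        )
    if pts.shape[0] < 2:
        raise InvalidStreamlineError("streamline needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise InvalidStreamlineError("streamline contains non-finite coordinates")
    return pts


def arc_length(s: Sequence | np.ndarray) -> float:
    """Total length (mm) of the polyline: the sum of consecutive chord lengths."""
    pts = as_streamline(s)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def resample(s: Sequence | np.ndarray, k: int) -> Streamline:
    """Resample a streamline to exactly *k* points equally spaced in arc length.

    The streamline is modelled as piecewise linear; the new points sit at
    arc lengths ``j * L / (k - 1)`` for ``j = 0 .. k-1`` where ``L`` is the
    total length.  The two endpoints are preserved bit-exactly.  A
    zero-length streamline (all points coincident) resamples to ``k``
    copies of the shared endpoint.

    Parameters
    ----------
    s : array-like, shape (n, 3)
        Input polyline, n >= 2.
    k : int
        Number of output points, k >= 2.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    pts = as_streamline(s)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    total = cum[-1]
    if total == 0.0:
        return np.repeat(pts[:1], k, axis=0)
    targets = np.linspace(0.0, total, k)
    out = np.empty((k, 3), dtype=np.float64)
    for dim in range(3):
        out[:, dim] = np.interp(targets, cum, pts[:, dim])
    # endpoints bit-exact regardless of interpolation round-off
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def flip(s: Sequence | np.ndarray) -> Streamline:
    """Return the point-reversed streamline ``s^F``; an involution."""
    return as_streamline(s)[::-1].copy()


@dataclass
class Tractography:
    """An ordered collection of streamlines with stable 1-based ids.

    Parameters
    ----------
    streamlines : list of (K_i, 3) arrays
        The polylines, in processing order.
    ids : array of int, optional
        Unique ids, one per streamline; defaults to ``1 .. N``.
    """

    streamlines: list[Streamline]
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.streamlines = [as_streamline(s) for s in self.streamlines]
        if self.ids is None:
            self.ids = np.arange(1, len(self.streamlines) + 1, dtype=np.int64)
        else:
            self.ids = np.asarray(self.ids, dtype=np.int64)
            if len(self.ids) != len(self.streamlines):
                raise ValueError("ids and streamlines must have equal length")
            if len(np.unique(self.ids)) != len(self.ids):
                raise ValueError("ids must be unique")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[Streamline]:
        return iter(self.streamlines)

    def items(self) -> Iterator[tuple[int, Streamline]]:
        """Iterate ``(id, streamline)`` pairs in processing order."""
        return zip(self.ids.tolist(), self.streamlines)

    def lengths(self) -> np.ndarray:
        """Arc length of every streamline, in order."""
        return np.array([arc_length(s) for s in self.streamlines])

    def resampled(self, k: int) -> "Tractography":
        """A copy with every streamline resampled to *k* points."""
        return Tractography([resample(s, k) for s in self.streamlines],
                            ids=self.ids.copy())

    def filter_by_length(self, min_len: float) -> "Tractography":
        """Keep streamlines with arc length >= *min_len* mm; ids preserved."""
        if min_len < 0:
            raise ValueError("min_len must be >= 0")
        keep = [i for i, s in enumerate(self.streamlines)
                if arc_length(s) >= min_len]
        return Tractography([self.streamlines[i] for i in keep],
                            ids=self.ids[keep])

    def permute(self, seed: int) -> "Tractography":
        """Deterministically shuffle processing order (ids travel with their
        streamlines); the same seed always yields the same order."""
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(self.streamlines))
        return Tractography([self.streamlines[i] for i in order],
                            ids=self.ids[order])

    @classmethod
    def concatenate(cls, parts: Iterable["Tractography"]) -> "Tractography":
        """Concatenate tractographies, renumbering ids to 1..N."""
        streamlines: list[Streamline] = []
        for part in parts:
            streamlines.extend(part.streamlines)
        return cls(streamlines)


def filter_by_length(t: Tractography, min_len: float) -> Tractography:
    """Functional alias for :meth:`Tractography.filter_by_length`."""
    return t.filter_by_length(min_len)


def permute(t: Tractography, seed: int) -> Tractography:
    """Functional alias for :meth:`Tractography.permute`."""
    return t.permute(seed)
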