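"""Streamline distance functions.

Two families are provided:

* **MDF** (minimum average direct-flip): for two streamlines with the same
  number of points K, the mean Euclidean distance between corresponding
  points is computed in both the direct and the point-reversed ("flipped")
  orientation, and the smaller of the two is taken.  MDF is a metric on the
  space of (directionless) streamlines and costs exactly 2K point-pair
  distances.

* **MAM** (minimum / mean / maximum average minimum): symmetric combinations
  of the two directed mean-of-minimum point-to-polyline distances.  MAM
  works on streamlines with different point counts, at a higher cost; the
  max variant is the classical Hausdorff-type mean distance.

All distances are in millimeters, double precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .streamlines import Streamline, as_streamline

__all__ = [
    "IncompatibleDiscretizationError",
    "MdfResult",
    "direct_distance",
    "flipped_distance",
    "mdf",
    "mdf_distance",
    "mdf_matrix",
    "point_to_streamline",
    "mam",
]


class IncompatibleDiscretizationError(ValueError):
    """MDF requires both streamlines to have the same number of points."""


@dataclass(frozen=True)
class MdfResult:
    """Outcome of one MDF evaluation.

    Attributes
    ----------
    direct : float
        Mean corresponding-point distance in the given orientation (mm).
    flipped : float
        Same with the second streamline point-reversed (mm).
    mdf : float
        ``min(direct, flipped)`` (mm).
    used_flip : bool
        True iff the flipped orientation is strictly smaller.
    """

    direct: float
    flipped: float
    mdf: float
    used_flip: bool


def _check_same_k(s: np.ndarray, t: np.ndarray) -> None:
    if s.shape[0] != t.shape[0]:
        raise IncompatibleDiscretizationError(
            f"MDF needs equal point counts, got {s.shape[0]} and {t.shape[0]}; "
            "resample both streamlines to a common K first"
        )


def direct_distance(s: Sequence | np.ndarray, t: Sequence | np.ndarray) -> float:
    """Mean Euclidean distance between corresponding points (mm).

    Both streamlines must have the same number of points K; the cost is K
    point-pair distances.
    """
    s = as_streamline(s)
    t = as_streamline(t)
    _check_same_k(s, t)
    return float(np.mean(np.linalg.norm(s - t, axis=1)))


def flipped_distance(s: Sequence | np.ndarray, t: Sequence | np.ndarray) -> float:
    """Mean corresponding-point distance with *t* point-reversed (mm)."""
    s = as_streamline(s)
    t = as_streamline(t)
    _check_same_k(s, t)
    return float(np.mean(np.linalg.norm(s - t[::-1], axis=1)))


def mdf(s: Sequence | np.ndarray, t: Sequence | np.ndarray) -> MdfResult:
    """Minimum average direct-flip distance between two equal-K streamlines.

    Returns the full :class:`MdfResult`; ties between the direct and the
    flipped orientation report ``used_flip=False`` (direct preferred).
    """
    s = as_streamline(s)
    t = as_streamline(t)
    _check_same_k(s, t)
    d = float(np.mean(np.linalg.norm(s - t, axis=1)))
    f = float(np.mean(np.linalg.norm(s - t[::-1], axis=1)))
    if f < d:
        return MdfResult(direct=d, flipped=f, mdf=f, used_flip=True)
    return MdfResult(direct=d, flipped=f, mdf=d, used_flip=False)


def mdf_distance(s: Sequence | np.ndarray, t: Sequence | np.ndarray) -> float:
    """Shorthand for ``mdf(s, t).mdf``."""
    return mdf(s, t).mdf


def mdf_matrix(S: Sequence[np.ndarray], T: Sequence[np.ndarray]) -> np.ndarray:
    """Pairwise MDF distances between two lists of equal-K streamlines.

    Returns an ``(|S|, |T|)`` array.  All streamlines must share the same
    point count K.  Vectorized over both sets; memory is O(|S|·|T|·K).
    """
    A = np.asarray([as_streamline(s) for s in S], dtype=np.float64)
    B = np.asarray([as_streamline(t) for t in T], dtype=np.float64)
    if A.shape[1] != B.shape[1]:
        raise IncompatibleDiscretizationError(
            f"MDF needs equal point counts, got {A.shape[1]} and {B.shape[1]}"
        )
    diff = A[:, None, :, :] - B[None, :, :, :]
    d = np.mean(np.sqrt(np.sum(diff * diff, axis=3)), axis=2)
    diff = A[:, None, :, :] - B[None, :, ::-1, :]
    f = np.mean(np.sqrt(np.sum(diff * diff, axis=3)), axis=2)
    return np.minimum(d, f)


def point_to_streamline(x: Sequence | np.ndarray, s: Sequence | np.ndarray) -> float:
    """Minimum Euclidean distance (mm) from point *x* to the vertices of *s*."""
    x = np.asarray(x, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if s.ndim != 2 or s.shape[0] < 1:
        raise ValueError("s must be a non-empty (K, 3) array")
    return float(np.min(np.linalg.norm(s - x, axis=1)))


def _directed_mean(s: np.ndarray, t: np.ndarray) -> float:
    """Mean over points of *s* of the min distance to the vertices of *t*."""
    return float(np.mean(np.min(cdist(s, t), axis=1)))


def mam(s: Sequence | np.ndarray, t: Sequence | np.ndarray,
        variant: str = "mean") -> float:
    """MAM distance between two streamlines of possibly different K.

    The directed mean distance ``d_mean(s, t)`` averages, over the points of
    *s*, the distance to the nearest vertex of *t*.  The two directed values
    are combined by *variant*:

    - ``"min"``  : ``min(d_mean(s,t), d_mean(t,s))`` — pulls short
      streamlines towards long ones; used to attach short streamlines to
      clusters of long ones.
    - ``"mean"`` : their average — the default, balanced behavior.
    - ``"max"``  : their maximum — the classical mean-Hausdorff flavor.

    All variants are symmetric in (s, t) and satisfy
    ``mam_min <= mam_mean <= mam_max``.
    """
    s = np.asarray(s, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if s.ndim != 2 or s.shape[0] < 1 or t.ndim != 2 or t.shape[0] < 1:
        from .streamlines import InvalidStreamlineError
        raise InvalidStreamlineError("mam requires non-empty point arrays")
    d_st = _directed_mean(s, t)
    d_ts = _directed_mean(t, s)
    if variant == "min":
        return min(d_st, d_ts)
    if variant == "max":
        return max(d_st, d_ts)
    if variant == "mean":
        return 0.5 * (d_st + d_ts)
    raise ValueError(f"variant must be one of 'min', 'mean', 'max', got {variant!r}")
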