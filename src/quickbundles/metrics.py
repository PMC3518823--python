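"""Statistics for comparing clusterings and streamline-set reductions.

Two clusterings of the *same* streamlines are compared through the
cross-classification matrix ``x_ij = |A_i ∩ B_j|`` and the optimized
matched agreement (OMA): the best injective cluster-to-cluster matching is
found by solving a linear assignment problem, and the matched agreement
``MA = Σ x_{i,π(i)}`` is reported as a percentage of the total streamline
count.  OMA is 100% for identical clusterings and reads like an
inter-rater Kappa (61–80% being good agreement).

Reductions of possibly *different* streamline sets are compared
geometrically through MDF adjacency at a threshold theta:

* ``coverage(S, T)`` — fraction of S lying within theta of some member of T;
* ``overlap(S, T)``  — mean number of T-neighbors per covered member of S
  (redundancy of the reduction; undefined when coverage is zero);
* ``bundle_adjacency(S, T)`` — symmetric mean of the two coverages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cluster import ClusterMap
from .distances import mdf_matrix

__all__ = [
    "UndefinedMetricError",
    "CrossClassificationMatrix",
    "MatchingResult",
    "cross_classification",
    "optimal_matching",
    "oma",
    "is_adjacent",
    "coverage",
    "overlap",
    "bundle_adjacency",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric's precondition (e.g. non-empty set) fails."""


def _as_partition(clustering) -> list[set[int]]:
    """Normalize a clustering (ClusterMap or iterable of id collections)."""
    if isinstance(clustering, ClusterMap):
        return clustering.partition()
    return [set(c) for c in clustering]


@dataclass(frozen=True)
class CrossClassificationMatrix:
    """Counts of streamlines shared by every pair of clusters across two
    clusterings of the same id set; rows index the first clustering."""

    x: np.ndarray  # (M, N) nonnegative integers

    @property
    def total(self) -> int:
        return int(self.x.sum())


@dataclass(frozen=True)
class MatchingResult:
    """Best injective row-to-column matching of a cross-classification
    matrix; ``pi`` maps row index to column index (zero-agreement pairs are
    dropped), ``matched_agreement`` is the summed matched counts and
    ``oma_percent`` that sum as a percentage of all counted streamlines."""

    pi: dict[int, int]
    matched_agreement: int
    oma_percent: float


def cross_classification(a, b) -> CrossClassificationMatrix:
    """Cross-classification matrix between two partitions of the same ids.

    Parameters may be :class:`ClusterMap` objects or iterables of id
    collections.  Raises if the two clusterings do not cover exactly the
    same id set.
    """
    pa = _as_partition(a)
    pb = _as_partition(b)
    ids_a = set().union(*pa) if pa else set()
    ids_b = set().union(*pb) if pb else set()
    if ids_a != ids_b:
        raise ValueError("clusterings must partition the same streamline id set")
    x = np.zeros((len(pa), len(pb)), dtype=np.int64)
    for i, ai in enumerate(pa):
        for j, bj in enumerate(pb):
            x[i, j] = len(ai & bj)
    return CrossClassificationMatrix(x=x)


def optimal_matching(x: CrossClassificationMatrix | np.ndarray) -> MatchingResult:
    """Injective cluster matching maximizing the matched agreement.

    Solved as a rectangular linear assignment (Hungarian-type) problem on
    the count matrix.  Matches that contribute zero agreement are dropped
    from the returned mapping.
    """
    m = x.x if isinstance(x, CrossClassificationMatrix) else np.asarray(x)
    if m.size == 0:
        raise ValueError("cross-classification matrix is empty")
    rows, cols = linear_sum_assignment(m, maximize=True)
    ma = int(m[rows, cols].sum())
    pi = {int(i): int(j) for i, j in zip(rows, cols) if m[i, j] > 0}
    total = int(m.sum())
    pct = 100.0 * ma / total if total > 0 else 0.0
    return MatchingResult(pi=pi, matched_agreement=ma, oma_percent=pct)


def oma(a, b) -> float:
    """Optimized matched agreement between two clusterings, in percent."""
    return optimal_matching(cross_classification(a, b)).oma_percent


def is_adjacent(s, T: Sequence, theta: float) -> bool:
    """True iff some member of T is within MDF <= theta of streamline s.

    Adjacency is non-strict (<=), unlike the clustering join rule which is
    strict; both follow the method's printed definitions.
    """
    if len(T) == 0:
        return False
    return bool(np.min(mdf_matrix([s], T)) <= theta)


def coverage(S: Sequence, T: Sequence, theta: float) -> float:
    """Fraction of S adjacent to T at MDF threshold theta; in [0, 1]."""
    if len(S) == 0:
        raise UndefinedMetricError("coverage of an empty set is undefined")
    if len(T) == 0:
        return 0.0
    d = mdf_matrix(S, T)
    return float(np.mean(np.any(d <= theta, axis=1)))


def overlap(S: Sequence, T: Sequence, theta: float) -> float:
    """Mean number of T-neighbors over the covered members of S; >= 1.

    Returns NaN (the undefined sentinel) when no member of S is adjacent
    to T.
    """
    if len(S) == 0 or len(T) == 0:
        return math.nan
    d = mdf_matrix(S, T)
    neighbor_counts = np.sum(d <= theta, axis=1)
    covered = neighbor_counts > 0
    if not np.any(covered):
        return math.nan
    return float(np.mean(neighbor_counts[covered]))


def bundle_adjacency(S: Sequence, T: Sequence, theta: float) -> float:
    """Symmetric similarity of two streamline sets: the mean of the two
    coverages at threshold theta; in [0, 1]."""
    if len(S) == 0 or len(T) == 0:
        raise UndefinedMetricError("bundle adjacency requires two non-empty sets")
    return 0.5 * (coverage(S, T, theta) + coverage(T, S, theta))
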