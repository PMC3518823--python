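"""Online streamline clustering with streamline-sum cluster nodes.

The algorithm makes a single pass over the tractography.  Each cluster is
held as a node ``(I, h, n)``: the member id list, the running element-wise
sum ``h`` of the (orientation-corrected) member streamlines, and the member
count.  The cluster centroid is ``v = h / n``, computed on the fly.  An
incoming streamline is compared by MDF against every current centroid; it
joins the nearest cluster if that distance is strictly below the threshold
``theta``, flipped first if the flipped orientation was the closer one, and
otherwise seeds a new cluster.  There is no reassignment phase: once placed,
a streamline stays put, which is what makes the pass linear-time on average.

Because only sums and counts are stored, memory per cluster is O(K) and an
insertion costs one MDF evaluation (2K point distances) per current cluster.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .streamlines import Streamline, Tractography, as_streamline, resample
from .distances import mam

__all__ = [
    "ClusterNode",
    "ClusterMap",
    "quickbundles",
    "centroid",
    "centroids",
    "select_largest",
    "compression_ratio",
    "assign_short_streamlines",
    "expand_cluster",
]


@dataclass
class ClusterNode:
    """One cluster: member ids ``I``, streamline sum ``h``, count ``n``.

    ``h`` is a (K, 3) array equal to the element-wise sum of the members in
    their orientation-corrected form; ``flips[j]`` records whether member
    ``I[j]`` was point-reversed before being added.
    """

    I: list[int]
    h: np.ndarray
    n: int
    flips: list[bool] = field(default_factory=list)

    def centroid(self) -> Streamline:
        """The centroid streamline ``v = h / n``."""
        return self.h / self.n


@dataclass
class ClusterMap:
    """Result of one clustering run: ordered cluster nodes plus run settings."""

    theta: float
    k: int
    nodes: list[ClusterNode] = field(default_factory=list)
    #: number of MDF evaluations performed so far (complexity monitoring)
    mdf_evaluations: int = 0

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    @property
    def n_streamlines(self) -> int:
        return sum(node.n for node in self.nodes)

    def sizes(self) -> list[int]:
        return [node.n for node in self.nodes]

    def partition(self) -> list[set[int]]:
        """Member-id sets, one per cluster, in creation order."""
        return [set(node.I) for node in self.nodes]

    def labels(self) -> dict[int, int]:
        """Map from streamline id to 1-based cluster id."""
        out: dict[int, int] = {}
        for ci, node in enumerate(self.nodes, start=1):
            for sid in node.I:
                out[sid] = ci
        return out

    def insert(self, sid: int, s: Streamline) -> int:
        """Online insertion of one K-point streamline; returns the 0-based
        index of the cluster it joined or created.

        This is the algorithm's single step: MDF against every current
        centroid, join the argmin cluster if its distance is strictly below
        ``theta`` (ties broken towards the lowest cluster index, and towards
        the direct orientation), else start a new cluster.
        """
        s = as_streamline(s)
        if s.shape[0] != self.k:
            raise ValueError(f"streamline has {s.shape[0]} points, expected K={self.k}")
        if not self.nodes:
            self.nodes.append(ClusterNode(I=[sid], h=s.copy(), n=1, flips=[False]))
            return 0
        # centroids of all current clusters, stacked: (M, K, 3)
        H = np.stack([node.h for node in self.nodes])
        counts = np.array([node.n for node in self.nodes], dtype=np.float64)
        V = H / counts[:, None, None]
        d = np.mean(np.linalg.norm(V - s, axis=2), axis=1)
        f = np.mean(np.linalg.norm(V - s[::-1], axis=2), axis=1)
        self.mdf_evaluations += len(self.nodes)
        use_flip = f < d          # strict: ties keep the direct orientation
        alld = np.where(use_flip, f, d)
        best = int(np.argmin(alld))   # argmin takes the lowest index on ties
        if alld[best] < self.theta:   # strict: MDF == theta starts a new cluster
            node = self.nodes[best]
            node.h = node.h + (s[::-1] if use_flip[best] else s)
            node.n += 1
            node.I.append(sid)
            node.flips.append(bool(use_flip[best]))
            return best
        self.nodes.append(ClusterNode(I=[sid], h=s.copy(), n=1, flips=[False]))
        return len(self.nodes) - 1


def quickbundles(t: Tractography, theta: float, k: int = 12) -> ClusterMap:
    """Cluster a tractography in one online pass.

    Parameters
    ----------
    t : Tractography
        Input streamlines; processed in their stored order, which makes the
        result order-dependent unless the bundles are separable at *theta*.
    theta : float
        Clustering threshold in mm; a streamline joins a cluster only if its
        MDF to the running centroid is strictly below *theta*.
    k : int
        Number of points per streamline; inputs with a different point count
        are resampled internally.

    Returns
    -------
    ClusterMap
        Partition of the input ids into clusters, with streamline sums.
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    cm = ClusterMap(theta=float(theta), k=int(k))
    for sid, s in t.items():
        if s.shape[0] != k:
            s = resample(s, k)
        cm.insert(sid, s)
    return cm


def centroid(c: ClusterNode) -> Streamline:
    """Centroid streamline of one cluster node, ``v = h / n``."""
    return c.centroid()


def centroids(cm: ClusterMap) -> list[Streamline]:
    """Centroid streamlines of all clusters, in creation order."""
    return [node.centroid() for node in cm.nodes]


def select_largest(cm: ClusterMap, m: int) -> ClusterMap:
    """The *m* biggest clusters (by member count) as a new map.

    Ties are broken towards the earlier-created cluster; if the map has
    fewer than *m* clusters they are all returned.  Nodes are ordered by
    decreasing size.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    order = sorted(range(len(cm.nodes)), key=lambda i: (-cm.nodes[i].n, i))
    picked = [copy.deepcopy(cm.nodes[i]) for i in order[:m]]
    return ClusterMap(theta=cm.theta, k=cm.k, nodes=picked,
                      mdf_evaluations=cm.mdf_evaluations)


def compression_ratio(n: int, cm: ClusterMap) -> float:
    """Tractography size divided by cluster count, N / M."""
    if len(cm.nodes) == 0:
        raise ValueError("cluster map is empty")
    return n / len(cm.nodes)


def assign_short_streamlines(long_cm: ClusterMap, shorts: Tractography,
                             link: str = "min",
                             pre_theta: float | None = None) -> ClusterMap:
    """Attach short streamlines to an existing clustering of long ones.

    Each short streamline (or, if *pre_theta* is given, each cluster of
    short streamlines produced by a separate clustering pass at that
    threshold) is appended to the long cluster whose centroid minimizes the
    MAM distance of the given *link* variant (default ``"min"``, which is
    the variant that pulls fragments towards full-length bundles).  Ties go
    to the lower-index cluster.  Shorts are resampled to the long map's K
    before the streamline sums are updated, with orientation chosen to
    minimize the corresponding-point distance to the target centroid.

    Returns a new ClusterMap; the input map is not modified.
    """
    if len(long_cm.nodes) == 0:
        raise ValueError("long cluster map is empty")
    out = ClusterMap(theta=long_cm.theta, k=long_cm.k,
                     nodes=[copy.deepcopy(node) for node in long_cm.nodes],
                     mdf_evaluations=long_cm.mdf_evaluations)

    if pre_theta is not None:
        short_cm = quickbundles(shorts, theta=pre_theta, k=long_cm.k)
        groups = [(node.centroid(), node.I) for node in short_cm.nodes]
        by_id = dict(shorts.items())
        member_lookup = lambda sid: by_id[sid]
    else:
        groups = [(s, [sid]) for sid, s in shorts.items()]
        member_lookup = dict(shorts.items()).__getitem__

    cents = [node.centroid() for node in out.nodes]
    for probe, sids in groups:
        dists = [mam(probe, c, variant=link) for c in cents]
        target = out.nodes[int(np.argmin(dists))]
        for sid in sids:
            s = resample(member_lookup(sid), out.k)
            d = np.mean(np.linalg.norm(target.centroid() - s, axis=1))
            f = np.mean(np.linalg.norm(target.centroid() - s[::-1], axis=1))
            use_flip = f < d
            target.h = target.h + (s[::-1] if use_flip else s)
            target.n += 1
            target.I.append(sid)
            target.flips.append(bool(use_flip))
    return out


def expand_cluster(seed_centroid: Streamline, t: Tractography,
                   mdf_thr: float, sub_thr: float, mam_thr: float,
                   k: int = 12) -> set[int]:
    """Grow a mixed long/short bundle from a single representative streamline.

    Three stages: (1) collect streamlines within *mdf_thr* (MDF, at K=*k*)
    of the seed; (2) re-cluster that set at the tighter threshold *sub_thr*;
    (3) sweep the whole tractography for streamlines within *mam_thr*
    (MAM min variant, on the original point sets) of any stage-2 centroid.
    Returns the union of the stage-1 and stage-3 id sets; empty if nothing
    passes stage 1.
    """
    if min(mdf_thr, sub_thr, mam_thr) <= 0:
        raise ValueError("all thresholds must be > 0")
    seed_k = resample(seed_centroid, k)
    rs = t.resampled(k)
    stage1_idx = []
    for idx, (sid, s) in enumerate(rs.items()):
        d = np.mean(np.linalg.norm(seed_k - s, axis=1))
        f = np.mean(np.linalg.norm(seed_k - s[::-1], axis=1))
        if min(d, f) <= mdf_thr:
            stage1_idx.append(idx)
    if not stage1_idx:
        return set()
    stage1_ids = {int(t.ids[i]) for i in stage1_idx}
    sub = Tractography([t.streamlines[i] for i in stage1_idx],
                       ids=t.ids[stage1_idx])
    sub_cm = quickbundles(sub, theta=sub_thr, k=k)
    sub_cents = centroids(sub_cm)
    stage3_ids: set[int] = set()
    for sid, s in t.items():
        if any(mam(s, c, variant="min") <= mam_thr for c in sub_cents):
            stage3_ids.add(int(sid))
    return stage1_ids | stage3_ids
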