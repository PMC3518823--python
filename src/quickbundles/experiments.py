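"""Robustness experiment drivers.

These reproduce, at desk scale, the standard stability checks for an
order-dependent online clustering:

* **permutation stability** — cluster the same tractography under several
  seeded shufflings of the processing order and summarize how the cluster
  count and the pairwise clustering agreement (OMA) vary;
* **centroids versus random subset** — split a tractography in half,
  cluster the first half, and compare its centroids against an equal-count
  random subset of streamlines as a reduction of the data, via coverage
  and overlap; the held-out second half measures generalization;
* **parallel-line phase** — on a uniformly spaced grid of parallel lines
  the clustering partitions the sheet into equal consecutive runs, and the
  OMA between two partitions ranges from 100% when their boundaries
  coincide down to 50% when they are offset by half a run width.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .cluster import centroids, quickbundles
from .metrics import coverage, oma, overlap
from .simulate import parallel_line_grid
from .streamlines import Tractography

__all__ = [
    "permutation_stability",
    "centroids_vs_random",
    "parallel_line_oma",
]


def permutation_stability(t: Tractography, theta: float, k: int = 12,
                          n_perms: int = 25, seed: int = 0) -> dict:
    """Cluster *t* under *n_perms* seeded random processing orders.

    Returns cluster counts per permutation with their mean/SD, and the mean
    OMA over all pairs of the resulting clusterings (each pair compared via
    the cross-classification matrix of the shared ids).
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    maps = [quickbundles(t.permute(seed + p), theta=theta, k=k)
            for p in range(n_perms)]
    counts = np.array([len(cm) for cm in maps])
    pair_omas = [oma(a, b) for a, b in combinations(maps, 2)]
    return {
        "n_permutations": n_perms,
        "cluster_counts": counts.tolist(),
        "cluster_count_mean": float(counts.mean()),
        "cluster_count_sd": float(counts.std(ddof=1)) if n_perms > 1 else 0.0,
        "mean_pairwise_oma": float(np.mean(pair_omas)) if pair_omas else 100.0,
    }


def centroids_vs_random(t: Tractography, theta: float, k: int = 12,
                        seed: int = 0, adjacency_theta: float | None = None) -> dict:
    """Compare cluster centroids against an equal-count random streamline
    subset as reductions of a tractography.

    The tractography is shuffled (seeded) and split into halves.  The first
    half is clustered at *theta*; its M centroids, and a random subset of M
    first-half streamlines, are each scored by coverage and overlap of the
    first half (the data they summarize) and of the held-out second half,
    at ``adjacency_theta`` (defaults to *theta*).
    """
    if adjacency_theta is None:
        adjacency_theta = theta
    shuffled = t.permute(seed)
    n_half = len(shuffled) // 2
    first = Tractography(shuffled.streamlines[:n_half], ids=shuffled.ids[:n_half])
    second = Tractography(shuffled.streamlines[n_half:], ids=shuffled.ids[n_half:])

    first_k = [s for s in first.resampled(k)]
    second_k = [s for s in second.resampled(k)]
    cm = quickbundles(first, theta=theta, k=k)
    cents = centroids(cm)
    rng = np.random.default_rng(seed + 1)
    pick = rng.choice(n_half, size=len(cents), replace=False)
    random_subset = [first_k[i] for i in pick]

    report: dict = {
        "theta": theta,
        "adjacency_theta": adjacency_theta,
        "n_first_half": n_half,
        "n_second_half": len(second_k),
        "n_centroids": len(cents),
    }
    for name, reducer in [("centroids", cents), ("random", random_subset)]:
        for half_name, half in [("first", first_k), ("second", second_k)]:
            report[f"coverage_{half_name}_{name}"] = coverage(
                half, reducer, adjacency_theta)
            report[f"overlap_{half_name}_{name}"] = overlap(
                half, reducer, adjacency_theta)
    return report


def parallel_line_oma(n_lines: int = 400, spacing: float = 1.0,
                      theta: float = 5.5, k: int = 12,
                      out_of_phase: bool = True) -> float:
    """OMA between two clusterings of a uniform parallel-line grid.

    Clustering the grid in spatial order partitions it into equal
    consecutive runs of lines.  With ``out_of_phase=False`` the same
    partition is compared with itself (OMA 100%).  With
    ``out_of_phase=True`` a second partition is obtained by clustering the
    grid extended with half a run of extra lines on one side and then
    restricting to the original lines, which shifts every run boundary by
    half a run width — the worst case, where OMA approaches 50% (up to
    edge runs).
    """
    grid = parallel_line_grid(n_lines, spacing=spacing)
    cm_a = quickbundles(grid, theta=theta, k=k)
    part_a = cm_a.partition()
    if not out_of_phase:
        part_b = quickbundles(grid, theta=theta, k=k).partition()
        return oma(part_a, part_b)
    run = cm_a.nodes[0].n
    q = max(1, run // 2)
    padded = parallel_line_grid(n_lines + q, spacing=spacing,
                                phase_offset=-q * spacing)
    cm_b = quickbundles(padded, theta=theta, k=k)
    # padded ids 1..q are the extra lines; id i+q is the original line i
    part_b = []
    for node in cm_b.nodes:
        kept = {sid - q for sid in node.I if sid > q}
        if kept:
            part_b.append(kept)
    return oma(part_a, part_b)
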