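# quickbundles

Online streamline clustering for diffusion-MRI tractography simplification.

Whole-brain tractographies contain 10⁵–10⁶ streamlines — far too many to
inspect, compare across subjects, or feed to interactive tools.  This
package reduces a tractography to a handful of representative *centroid
streamlines* with a single linear-time pass, and ships the statistics
needed to judge how faithful that reduction is.  It is aimed at
neuroimaging researchers working with TrackVis `.trk` tractograms or any
collection of 3-D polylines in millimeter coordinates.

## The method

Every streamline is resampled to a fixed number of points K (default 12)
at equal arc-length spacing, keeping the endpoints intact.  Two equal-K
streamlines *s*, *t* are compared with the **minimum average direct-flip
(MDF)** distance

```
d_direct(s, t) = (1/K) Σᵢ |sᵢ − tᵢ|
MDF(s, t)      = min(d_direct(s, t), d_direct(s, tᶠ))
```

where *tᶠ* is *t* with its points reversed — streamlines have no preferred
orientation.  MDF is a metric on streamline space and costs only 2K
point-pair distances.

Clustering is a single ordered pass.  Each cluster is a node
*c = (I, h, n)*: the member id list, the element-wise **streamline sum**
*h* of the (orientation-corrected) members, and the count *n*; the
centroid is *v = h/n*, computed on the fly.  An incoming streamline joins
the cluster whose centroid is nearest by MDF if that distance is strictly
below a threshold θ (flipped first if that orientation was closer), and
otherwise seeds a new cluster.  Nothing is ever reassigned, which is what
makes the pass O(MN) for M final clusters — linear in N at fixed scene
complexity.

Reductions and clusterings are scored with:

* **OMA** (optimized matched agreement): the best injective
  cluster-to-cluster matching between two clusterings of the same
  streamlines (Hungarian assignment on the cross-classification matrix
  x_ij = |A_i ∩ B_j|), reported as a percentage of all streamlines;
* **coverage / overlap**: the fraction of a streamline set within an MDF
  adjacency threshold of a reduced set, and the mean number of reduced-set
  neighbors per covered streamline (redundancy);
* **bundle adjacency**: the symmetric mean of the two coverages.

For streamlines of unequal point counts (e.g. short fragments) the
**MAM** family (min/mean/max combinations of directed mean nearest-vertex
distances) supports attaching fragments to long-streamline clusters and
growing mixed long/short bundles from a single representative.

## Worked example

```python
from quickbundles import (three_bundle_phantom, quickbundles, compression_ratio,
                          centroids, coverage, overlap, permutation_stability)

t, labels = three_bundle_phantom(seed=0)       # 450 synthetic streamlines
for theta in (1.0, 8.0):
    cm = quickbundles(t, theta=theta, k=12)
    print(f"theta={theta:4.1f} mm: N={len(t)}, M={len(cm)} clusters, "
          f"compression {compression_ratio(len(t), cm):.1f}:1")

cm = quickbundles(t, theta=8.0, k=12)
cents = centroids(cm)
full = [s for s in t.resampled(12)]
print(f"coverage of the phantom by {len(cents)} centroids at 10 mm: "
      f"{coverage(full, cents, 10.0):.3f}")
print(f"overlap (mean centroids within 10 mm per streamline): "
      f"{overlap(full, cents, 10.0):.2f}")

rep = permutation_stability(t, theta=8.0, k=12, n_perms=6, seed=0)
print(f"cluster count over 6 shuffles: {rep['cluster_count_mean']:.1f} "
      f"+/- {rep['cluster_count_sd']:.1f}; mean pairwise OMA "
      f"{rep['mean_pairwise_oma']:.1f}%")
```

prints

```
theta= 1.0 mm: N=450, M=29 clusters, compression 15.5:1
theta= 8.0 mm: N=450, M=3 clusters, compression 150.0:1
coverage of the phantom by 3 centroids at 10 mm: 1.000
overlap (mean centroids within 10 mm per streamline): 1.04
cluster count over 6 shuffles: 4.2 +/- 0.4; mean pairwise OMA 91.2%
```

The phantom has three ground-truth bundles (a helix pencil, a fan of bent
rays hugging the helix axis, and a distant corrugated fan).  At a fine
1 mm threshold the pass splits them into 29 label-pure sub-clusters; at a
coarse 8 mm threshold the helix and bent-ray bundles merge into one
cluster while the distant fan stays separate, so 3 centroids summarize all
450 streamlines (150:1 compression) with perfect coverage and essentially
no redundancy (overlap ≈ 1).  Because the pass is order-dependent,
reshuffled runs vary slightly; their pairwise OMA of 91% indicates the
partitions stay substantially the same.

## Command line

```
qb simulate phantom --seed 0 --out phantom.trk --labels truth.txt
qb cluster --in phantom.trk --threshold 8 --out-centroids cents.trk --out-labels labels.txt
qb metrics ba --set-a cents.trk --set-b cents.trk --theta 10
qb experiment stability --in phantom.trk --threshold 8 --n-perms 10
```

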