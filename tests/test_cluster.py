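"""The online clustering pass, cluster nodes and derived operations."""

import numpy as np
import pytest

from quickbundles import (
    ClusterMap,
    Tractography,
    assign_short_streamlines,
    centroid,
    centroids,
    compression_ratio,
    expand_cluster,
    flip,
    mdf_matrix,
    quickbundles,
    resample,
    select_largest,
    truncate_copies,
)
from conftest import random_streamline


def _line(y, k=3, x_max=2.0):
    x = np.linspace(0.0, x_max, k)
    return np.column_stack([x, np.full(k, float(y)), np.zeros(k)])


def test_single_streamline(rng):
    s = random_streamline(rng, 12)
    cm = quickbundles(Tractography([s]), theta=5.0, k=12)
    assert len(cm) == 1 and cm.nodes[0].n == 1
    np.testing.assert_allclose(centroid(cm.nodes[0]), s)  # 12 points: used as-is


def test_flip_bookkeeping(rng):
    s = resample(random_streamline(rng, 12), 12)
    cm = quickbundles(Tractography([s, flip(s)]), theta=1e6, k=12)
    assert len(cm) == 1
    node = cm.nodes[0]
    assert node.n == 2 and node.flips == [False, True]
    np.testing.assert_allclose(node.h, 2 * s, atol=1e-9)
    np.testing.assert_allclose(centroid(node), s, atol=1e-9)


def test_hand_traced_three_lines():
    """Lines at y=0,1,2 with theta=1.5: y=1 joins y=0 (distance 1 < 1.5,
    centroid moves to y=0.5), then y=2 is exactly 1.5 from the running
    centroid and the strict join rule starts a new cluster."""
    t = Tractography([_line(0), _line(1), _line(2)])
    cm = quickbundles(t, theta=1.5, k=3)
    assert cm.partition() == [{1, 2}, {3}]
    np.testing.assert_allclose(centroid(cm.nodes[0])[:, 1], 0.5)


def test_theta_equal_distance_starts_new_cluster():
    t = Tractography([_line(0), _line(1)])
    assert len(quickbundles(t, theta=1.0, k=3)) == 2      # 1.0 not < 1.0
    assert len(quickbundles(t, theta=1.0 + 1e-9, k=3)) == 1


def test_partition_property(random_tractography):
    t = random_tractography(80)
    cm = quickbundles(t, theta=40.0, k=12)
    parts = cm.partition()
    all_ids = set().union(*parts)
    assert all_ids == set(t.ids.tolist())
    assert sum(len(p) for p in parts) == len(t)  # no id in two clusters
    assert cm.n_streamlines == len(t)


def test_online_equivalence(random_tractography, rng):
    """Clustering T then streaming one more streamline equals clustering
    T + [s] in a single call: there is no reassignment phase."""
    t = random_tractography(40)
    extra = resample(random_streamline(rng, 20), 12)
    whole = Tractography(t.streamlines + [extra])
    cm_whole = quickbundles(whole, theta=35.0, k=12)
    cm_inc = quickbundles(t, theta=35.0, k=12)
    cm_inc.insert(41, extra)
    assert cm_inc.partition() == cm_whole.partition()
    for a, b in zip(cm_inc.nodes, cm_whole.nodes):
        np.testing.assert_allclose(a.h, b.h, atol=1e-9)


def test_separable_bundles_are_order_invariant():
    """When bundles are tight relative to theta and far apart, every
    processing order yields the same partition."""
    bundles = [[_line(base + d, k=12, x_max=50) for d in (0.0, 0.3, 0.6)]
               for base in (0.0, 30.0, 60.0)]
    t = Tractography([s for b in bundles for s in b])
    reference = None
    for seed in range(10):
        p = t.permute(seed)
        parts = {frozenset(c) for c in quickbundles(p, theta=2.0, k=12).partition()}
        if reference is None:
            reference = parts
        assert parts == reference
    assert len(reference) == 3


def test_worst_case_all_singletons():
    t = Tractography([_line(10.0 * j, k=12, x_max=50) for j in range(20)])
    cm = quickbundles(t, theta=1.0, k=12)
    assert len(cm) == 20
    assert all(node.n == 1 for node in cm.nodes)
    # every insertion compared against every existing cluster: N(N-1)/2
    assert cm.mdf_evaluations == 20 * 19 // 2


def test_mdf_evaluation_budget(random_tractography):
    t = random_tractography(60)
    cm = quickbundles(t, theta=30.0, k=12)
    assert 0 < cm.mdf_evaluations <= len(t) * len(cm)


def test_centroid_brute_force_oracle(phantom):
    """h/n equals the from-scratch mean of flip-corrected members on every
    cluster of the phantom."""
    t, _ = phantom
    rs = t.resampled(12)
    by_id = dict(rs.items())
    cm = quickbundles(t, theta=8.0, k=12)
    for node in cm.nodes:
        members = [by_id[sid][::-1] if flipped else by_id[sid]
                   for sid, flipped in zip(node.I, node.flips)]
        np.testing.assert_allclose(centroid(node), np.mean(members, axis=0),
                                   atol=1e-9)


def test_centroids_listing(phantom):
    t, _ = phantom
    cm = quickbundles(t, theta=8.0, k=12)
    cents = centroids(cm)
    assert len(cents) == len(cm)
    assert all(c.shape == (12, 3) for c in cents)
    empty = ClusterMap(theta=1.0, k=12)
    assert centroids(empty) == []


def test_select_largest_tie_rule():
    t = Tractography([_line(0), _line(0.1), _line(0.2), _line(0.3), _line(0.4),
                      _line(10), _line(10.1), _line(10.2),
                      _line(20), _line(20.1), _line(20.2),
                      _line(30)])
    cm = quickbundles(t, theta=1.0, k=3)
    assert cm.sizes() == [5, 3, 3, 1]
    top2 = select_largest(cm, 2)
    assert top2.sizes() == [5, 3]
    assert top2.nodes[1].I == cm.nodes[1].I  # earlier-created 3 wins the tie
    assert select_largest(cm, 1).sizes() == [5]
    assert select_largest(cm, 99).sizes() == [5, 3, 3, 1]


def test_compression_ratio(phantom):
    t, _ = phantom
    cm = quickbundles(t, theta=8.0, k=12)
    assert compression_ratio(len(t), cm) == len(t) / len(cm)
    single = quickbundles(Tractography([_line(0)]), theta=1.0, k=3)
    assert compression_ratio(1, single) == 1.0
    assert compression_ratio(100, select_largest(cm, 4)) == pytest.approx(
        100 / min(4, len(cm)))


def test_empty_tractography_gives_empty_map():
    cm = quickbundles(Tractography([]), theta=5.0, k=12)
    assert len(cm) == 0
    with pytest.raises(ValueError):
        quickbundles(Tractography([]), theta=-1.0, k=12)


def test_assign_shorts_to_coincident_centroid():
    longs = Tractography([_line(0, k=12, x_max=100), _line(20, k=12, x_max=100)])
    cm = quickbundles(longs, theta=1.0, k=12)
    # a fragment lying on the first centroid: MAM_min is 0 there
    frag = np.column_stack([np.linspace(30, 60, 5), np.zeros(5), np.zeros(5)])
    out = assign_short_streamlines(cm, Tractography([frag], ids=[99]))
    assert 99 in out.nodes[0].I and 99 not in out.nodes[1].I
    assert out.nodes[0].n == cm.nodes[0].n + 1
    assert len(cm.nodes[0].I) == 1  # input map untouched


def test_assign_shorts_tie_goes_to_lower_index():
    longs = Tractography([_line(0, k=12, x_max=100), _line(10, k=12, x_max=100)])
    cm = quickbundles(longs, theta=1.0, k=12)
    mid = np.column_stack([np.linspace(0, 100, 5), np.full(5, 5.0), np.zeros(5)])
    out = assign_short_streamlines(cm, Tractography([mid], ids=[7]))
    assert 7 in out.nodes[0].I


def test_assign_truncated_copies_return_to_parent(phantom):
    t, labels = phantom
    # two well-separated parents, one per far-apart bundle
    parents = Tractography([t.streamlines[0], t.streamlines[310]], ids=[1, 2])
    cm = quickbundles(parents, theta=1.0, k=12)
    shorts = truncate_copies(parents, fraction_range=(0.4, 0.6),
                             per_streamline=3, seed=1)
    out = assign_short_streamlines(cm, Tractography(shorts.streamlines,
                                                    ids=np.arange(10, 16)))
    # brute-force nearest-centroid oracle
    from quickbundles import mam
    cents = centroids(cm)
    for sid, s in zip(range(10, 16), shorts.streamlines):
        expected = int(np.argmin([mam(s, c, "min") for c in cents]))
        assert sid in out.nodes[expected].I


def test_assign_shorts_with_preclustering(phantom):
    t, _ = phantom
    parents = Tractography([t.streamlines[0], t.streamlines[310]], ids=[1, 2])
    cm = quickbundles(parents, theta=1.0, k=12)
    shorts = truncate_copies(parents, fraction_range=(0.5, 0.6),
                             per_streamline=2, seed=3)
    out = assign_short_streamlines(cm, shorts, pre_theta=30.0)
    assert out.n_streamlines == cm.n_streamlines + len(shorts)
    with pytest.raises(ValueError):
        assign_short_streamlines(ClusterMap(theta=1.0, k=12), shorts)


def test_expand_cluster_stages():
    # a long bundle near y=0, a disjoint far bundle at y=500
    longs = [_line(d, k=40, x_max=100) for d in (0.0, 1.0, 2.0)]
    far = [_line(500.0 + d, k=40, x_max=100) for d in (0.0, 1.0)]
    # short fragments lying along the long bundle: rejected by MDF at
    # stage 1 (poor correspondence), captured by MAM_min at stage 3
    frags = [np.column_stack([np.linspace(20, 45, 10), np.full(10, 1.0),
                              np.zeros(10)]),
             np.column_stack([np.linspace(60, 80, 10), np.full(10, 0.5),
                              np.zeros(10)])]
    t = Tractography(longs + far + frags)
    seed = longs[0]
    got = expand_cluster(seed, t, mdf_thr=5.0, sub_thr=3.0, mam_thr=3.5, k=12)
    assert got == {1, 2, 3, 6, 7}  # bundle + fragments, far bundle excluded
    # fragments are not within the stage-1 MDF radius of the seed
    rs = t.resampled(12)
    D = mdf_matrix([resample(seed, 12)], list(rs))
    assert D[0, 5] > 5.0 and D[0, 6] > 5.0

    only_seed = Tractography([seed])
    assert expand_cluster(seed, only_seed, 5.0, 3.0, 2.0, k=12) == {1}
    far_only = Tractography(far)
    assert expand_cluster(seed, far_only, 5.0, 3.0, 2.0, k=12) == set()
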