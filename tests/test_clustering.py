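"""Canberra distance and Ward.D2 linkage, checked against an independent
per-step Ward-criterion oracle and scipy, plus leaf-order contracts."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import canberra as scipy_canberra
from scipy.spatial.distance import squareform

from dormantx.cluster import (Dendrogram, DimensionError,
                              MatrixValidationError, canberra_distance,
                              cluster_matrix, leaf_order, pairwise_canberra,
                              ward_d2_linkage)


# -- Canberra -----------------------------------------------------------------

@pytest.mark.parametrize("x, y, expected", [
    ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
    ([1.0, 0.0], [0.0, 1.0], 2.0),
    ([0.0, 3.0], [0.0, 1.0], 0.5),
])
def test_canberra_hand_values(x, y, expected):
    assert canberra_distance(x, y) == pytest.approx(expected)


def test_canberra_length_mismatch():
    with pytest.raises(DimensionError):
        canberra_distance([1.0], [1.0, 2.0])


def test_canberra_matches_scipy_and_metric_axioms(rng):
    for _ in range(200):
        x, y, z = rng.normal(size=(3, 8)) * rng.integers(0, 2, size=(3, 8))
        dxy = canberra_distance(x, y)
        assert dxy == pytest.approx(scipy_canberra(x, y), abs=1e-12)
        assert dxy == pytest.approx(canberra_distance(y, x))
        assert dxy >= 0
        # triangle inequality on the sampled triple
        assert dxy <= (canberra_distance(x, z) + canberra_distance(z, y)
                       + 1e-12)
    a = np.array([1.0, 2.0, 0.0])
    assert canberra_distance(a, a) == 0.0


# -- independent Ward oracle --------------------------------------------------

def ward_cost_from_original(d2, members_a, members_b):
    """Squared Ward.D2 merge height computed from the *original* squared
    distances via the centroid identity, not the Lance-Williams recursion:

        ||mu_A - mu_B||^2 = mean cross d2 - half mean within-A d2
                                          - half mean within-B d2
        height^2 = 2 |A||B| / (|A|+|B|) * ||mu_A - mu_B||^2
    """
    na, nb = len(members_a), len(members_b)
    cross = sum(d2[i, j] for i in members_a for j in members_b) / (na * nb)
    within_a = sum(d2[i, j] for i in members_a for j in members_a) / (
        2 * na * na)
    within_b = sum(d2[i, j] for i in members_b for j in members_b) / (
        2 * nb * nb)
    mu_dist = cross - within_a - within_b
    return 2.0 * na * nb / (na + nb) * mu_dist


def ward_oracle(dist):
    """Greedy Ward.D2 evaluating the criterion over all active pairs at
    each step, with smallest-(a, b) tie-breaking."""
    n = dist.shape[0]
    d2 = dist.astype(float) ** 2
    clusters = {i: [i] for i in range(n)}
    merges = []
    for t in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            cost = ward_cost_from_original(d2, clusters[a], clusters[b])
            if best is None or cost < best[0] - 1e-12 or (
                    abs(cost - best[0]) <= 1e-12 and (a, b) < best[1:]):
                best = (cost, a, b)
        cost, a, b = best
        new = n + t
        clusters[new] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, np.sqrt(max(cost, 0.0)), len(clusters[new])))
    return merges


def random_distance_matrix(rng, n):
    points = rng.normal(size=(n, 3))
    return np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))


def test_two_points_merge_at_their_distance():
    dist = np.array([[0.0, 3.5], [3.5, 0.0]])
    dend = ward_d2_linkage(dist, leaves=["a", "b"])
    (a, b, height, size), = dend.merges
    assert (a, b, size) == (0, 1, 2)
    assert height == pytest.approx(3.5)


def test_duplicate_points_first_merge_at_zero(rng):
    points = rng.normal(size=(4, 2))
    points[1] = points[0]
    dist = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    dend = ward_d2_linkage(dist)
    assert dend.merges[0][2] == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("n", [3, 4, 5, 6])
def test_linkage_matches_per_step_ward_criterion_oracle(rng, n):
    for _ in range(20):
        dist = random_distance_matrix(rng, n)
        dend = ward_d2_linkage(dist)
        expected = ward_oracle(dist)
        for got, want in zip(dend.merges, expected):
            assert got[:2] == want[:2]
            assert got[2] == pytest.approx(want[2], abs=1e-9)
            assert got[3] == want[3]


def test_linkage_matches_scipy_cophenetic_structure(rng):
    """Same tree as scipy's ward linkage, compared order-independently
    through cophenetic distances."""
    for _ in range(20):
        dist = random_distance_matrix(rng, 8)
        dend = ward_d2_linkage(dist)
        ours = cophenet(dend.to_scipy_linkage())
        theirs = cophenet(linkage(squareform(dist, checks=False), "ward"))
        assert np.allclose(ours, theirs, atol=1e-8)


def test_heights_non_decreasing(rng):
    dist = random_distance_matrix(rng, 12)
    heights = [m[2] for m in ward_d2_linkage(dist).merges]
    assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))


def test_matrix_validation():
    with pytest.raises(MatrixValidationError):
        ward_d2_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
    with pytest.raises(MatrixValidationError):
        ward_d2_linkage(np.array([[0.0, -1.0], [-1.0, 0.0]]))  # negative


# -- leaf order ---------------------------------------------------------------

def test_single_leaf_order():
    dend = Dendrogram(merges=[], leaves=["only"])
    assert leaf_order(dend) == ["only"]
    assert dend.to_newick() == "only;"


def test_leaf_order_is_permutation(rng):
    dist = random_distance_matrix(rng, 9)
    labels = [f"L{i}" for i in range(9)]
    dend = ward_d2_linkage(dist, leaves=labels)
    assert sorted(leaf_order(dend)) == sorted(labels)


def test_planted_clusters_contiguous_in_leaf_order(rng):
    """Two well-separated blobs stay contiguous in the leaf order."""
    a = rng.normal(0.0, 0.5, size=(5, 3))
    b = rng.normal(20.0, 0.5, size=(5, 3))
    points = np.vstack([a, b])
    dist = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    labels = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
    order = leaf_order(ward_d2_linkage(dist, leaves=labels))
    groups = [lab[0] for lab in order]
    assert groups == sorted(groups) or groups == sorted(groups, reverse=True)


def test_newick_export_parses_with_biopython(tmp_path, rng):
    from io import StringIO
    from Bio import Phylo
    dist = random_distance_matrix(rng, 6)
    dend = ward_d2_linkage(dist, leaves=[f"L{i}" for i in range(6)])
    tree = Phylo.read(StringIO(dend.to_newick()), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == [
        f"L{i}" for i in range(6)]


def test_cluster_matrix_smoke(rng):
    import pandas as pd
    values = pd.DataFrame(rng.normal(5, 1, size=(12, 6)).clip(0.1),
                          index=[f"g{i}" for i in range(12)],
                          columns=[f"s{j}" for j in range(6)])
    dend, order = cluster_matrix(values, axis="columns")
    assert sorted(order) == sorted(values.columns)
    dend2 = pairwise_canberra(values.to_numpy())
    assert dend2.shape == (12, 12) and np.allclose(np.diag(dend2), 0.0)
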