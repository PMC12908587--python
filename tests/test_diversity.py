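"""Tests for diversity metrics, ordination and group-structure tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from gmadapt import diversity as dv
from gmadapt import synth


# ---------------------------------------------------------------------------
# Brute-force oracles


def faith_oracle(present, tree):
    """Sum of branch lengths on the union of root-to-leaf paths."""
    edges = set()
    for tip in tree.tips():
        if tip.name not in present:
            continue
        node = tip
        while node.parent is not None:
            edges.add(id(node))
            node = node.parent
    total = 0.0
    for node in tree.traverse(include_self=False):
        if id(node) in edges and node.length is not None:
            total += node.length
    return total


def wuf_oracle(x, y, ids, tree):
    """Per-branch summation of weighted UniFrac."""
    lookup = dict(zip(ids, range(len(ids))))
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            continue
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        a = sum(x[lookup[t]] for t in tips if t in lookup)
        b = sum(y[lookup[t]] for t in tips if t in lookup)
        num += node.length * abs(a - b)
        den += node.length * (a + b)
    return num / den


# ---------------------------------------------------------------------------
# Shannon


def test_shannon_uniform():
    assert dv.shannon(np.full(10, 0.1)) == pytest.approx(np.log(10))


def test_shannon_single_species():
    assert dv.shannon([1.0, 0.0, 0.0]) == 0.0


def test_shannon_hand_example():
    assert dv.shannon([0.5, 0.25, 0.25]) == pytest.approx(1.039721, abs=1e-6)


def test_shannon_negative_raises():
    with pytest.raises(ValueError):
        dv.shannon([-0.1, 1.1])


def test_shannon_maximised_by_uniform(rng):
    s = 12
    uniform = dv.shannon(np.full(s, 1.0 / s))
    for _ in range(50):
        p = rng.dirichlet(np.ones(s))
        assert dv.shannon(p) <= uniform + 1e-12


# ---------------------------------------------------------------------------
# Faith PD


def test_faith_all_species_is_total_length(small_tree):
    total = sum(
        n.length for n in small_tree.traverse(include_self=False)
        if n.length is not None
    )
    assert dv.faith_pd(["a", "b", "c", "d", "e"], small_tree) == pytest.approx(total)


def test_faith_single_species_is_path(small_tree):
    tip = next(t for t in small_tree.tips() if t.name == "c")
    path = 0.0
    node = tip
    while node.parent is not None:
        path += node.length
        node = node.parent
    assert dv.faith_pd(["c"], small_tree) == pytest.approx(path)


def test_faith_missing_species_raises(small_tree):
    with pytest.raises(ValueError, match="absent"):
        dv.faith_pd(["a", "zzz"], small_tree)


def test_faith_matches_oracle_random_subsets(rng):
    for rep in range(50):
        n = int(rng.integers(3, 9))
        ids = [f"t{i}" for i in range(n)]
        tree = synth.generate_tree(ids, seed=rep)
        k = int(rng.integers(1, n + 1))
        present = list(rng.choice(ids, size=k, replace=False))
        assert dv.faith_pd(present, tree) == pytest.approx(
            faith_oracle(set(present), tree), abs=1e-12
        )


# ---------------------------------------------------------------------------
# Bray-Curtis


def test_bray_curtis_examples():
    assert dv.bray_curtis([0.5, 0.5], [0.5, 0.5]) == 0.0
    assert dv.bray_curtis([1.0, 0.0], [0.0, 1.0]) == 1.0
    assert dv.bray_curtis([0.7, 0.3], [0.3, 0.7]) == pytest.approx(0.4)


def test_bray_curtis_all_zero_raises():
    with pytest.raises(ValueError):
        dv.bray_curtis([0.0, 0.0], [0.0, 0.0])


# ---------------------------------------------------------------------------
# Weighted UniFrac


def test_wuf_identity(small_tree, rng):
    x = rng.dirichlet(np.ones(5))
    assert dv.weighted_unifrac(x, x, ["a", "b", "c", "d", "e"], small_tree) == 0.0


def test_wuf_two_leaf_disjoint():
    tree = synth.generate_tree(["a", "b"], seed=0)
    assert dv.weighted_unifrac(
        [1.0, 0.0], [0.0, 1.0], ["a", "b"], tree
    ) == pytest.approx(1.0)


def test_wuf_matches_oracle_random(rng):
    for rep in range(100):
        n = int(rng.integers(2, 9))
        ids = [f"t{i}" for i in range(n)]
        tree = synth.generate_tree(ids, seed=1000 + rep)
        x = rng.dirichlet(np.ones(n))
        y = rng.dirichlet(np.ones(n))
        assert dv.weighted_unifrac(x, y, ids, tree) == pytest.approx(
            wuf_oracle(x, y, ids, tree), abs=1e-12
        )


def test_metric_properties(rng):
    ids = [f"t{i}" for i in range(6)]
    tree = synth.generate_tree(ids, seed=3)
    for _ in range(20):
        x = rng.dirichlet(np.ones(6))
        y = rng.dirichlet(np.ones(6))
        w_xy = dv.weighted_unifrac(x, y, ids, tree)
        w_yx = dv.weighted_unifrac(y, x, ids, tree)
        assert w_xy == pytest.approx(w_yx, abs=1e-12)
        assert 0.0 <= w_xy <= 1.0
        bc = dv.bray_curtis(x, y)
        assert bc == pytest.approx(dv.bray_curtis(y, x), abs=1e-12)
        assert 0.0 <= bc <= 1.0


def test_beta_diversity_matrix_consistency(default_study):
    table = default_study.abundance.iloc[:6]
    d = dv.beta_diversity(table, "weighted_unifrac", tree=default_study.tree)
    mat = table.to_numpy()
    ids = list(table.columns)
    for i in range(6):
        assert d.iloc[i, i] == 0.0
        for j in range(i + 1, 6):
            ref = dv.weighted_unifrac(mat[i], mat[j], ids, default_study.tree)
            assert d.iloc[i, j] == pytest.approx(ref, abs=1e-12)
            assert d.iloc[j, i] == d.iloc[i, j]


# ---------------------------------------------------------------------------
# PCoA


def test_pcoa_equilateral_triangle():
    d = np.ones((3, 3)) - np.eye(3)
    res = dv.pcoa(d)
    assert res.eigenvalues == pytest.approx([0.5, 0.5], abs=1e-9)
    assert res.coordinates.shape == (3, 2)


def test_pcoa_reconstructs_euclidean_distances(rng):
    pts = rng.standard_normal((8, 3))
    d = squareform(pdist(pts))
    res = dv.pcoa(d)
    recon = squareform(pdist(res.coordinates))
    assert np.allclose(recon, d, atol=1e-9)
    assert res.negative_eigenvalue_mass == pytest.approx(0.0, abs=1e-9)


def test_pcoa_duplicate_rows_identical_coords(rng):
    pts = rng.standard_normal((6, 3))
    pts[5] = pts[0]
    d = squareform(pdist(pts))
    res = dv.pcoa(d)
    assert np.allclose(res.coordinates[0], res.coordinates[5], atol=1e-9)


def test_pcoa_eigenvalues_sorted_positive(default_study):
    d = dv.beta_diversity(
        default_study.abundance, "bray_curtis"
    )
    res = dv.pcoa(d)
    assert np.all(np.diff(res.eigenvalues) <= 1e-12)
    assert np.all(res.eigenvalues > 0)


def test_pcoa_asymmetric_raises():
    d = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        dv.pcoa(d)


# ---------------------------------------------------------------------------
# PERMANOVA


def test_permanova_separated_clusters(rng):
    pts = np.vstack(
        [rng.normal(0, 0.1, (8, 3)), rng.normal(10, 0.1, (8, 3))]
    )
    d = squareform(pdist(pts))
    labels = np.array(["a"] * 8 + ["b"] * 8)
    f, p = dv.permanova(d, labels, n_perm=999, seed=0)
    assert p == pytest.approx(1.0 / 1000.0)
    assert f > 100


def test_permanova_invariant_to_sample_order(rng):
    pts = rng.standard_normal((12, 3))
    d = squareform(pdist(pts))
    labels = np.array(["a"] * 6 + ["b"] * 6)
    f1, _ = dv.permanova(d, labels, n_perm=9, seed=0)
    perm = rng.permutation(12)
    f2, _ = dv.permanova(d[np.ix_(perm, perm)], labels[perm], n_perm=9, seed=0)
    assert f1 == pytest.approx(f2, abs=1e-12)


def test_permanova_null_calibration():
    rejections = []
    labels = np.array(["a"] * 8 + ["b"] * 8)
    for seed in range(200):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((16, 4))
        d = squareform(pdist(pts))
        _, p = dv.permanova(d, labels, n_perm=99, seed=seed)
        rejections.append(p <= 0.05)
    assert 0.02 <= np.mean(rejections) <= 0.09


def test_permanova_small_group_raises():
    d = np.zeros((4, 4))
    with pytest.raises(ValueError, match="fewer than 2"):
        dv.permanova(d, ["a", "a", "a", "b"], n_perm=9)


# ---------------------------------------------------------------------------
# Dispersion


def test_dispersion_scaled_group_detected(rng):
    pts = np.vstack(
        [rng.normal(0, 1.0, (10, 3)) * 3.0, rng.normal(0, 1.0, (10, 3))]
    )
    d = squareform(pdist(pts))
    labels = np.array(["wide"] * 10 + ["tight"] * 10)
    res = dv.dispersion_test(d, labels, n_perm=999, seed=1)
    assert res.p <= 0.01
    z_wide = res.centroid_distances[labels == "wide"].mean()
    z_tight = res.centroid_distances[labels == "tight"].mean()
    assert z_wide > z_tight


def test_dispersion_identical_groups_f_zero(rng):
    pts = rng.standard_normal((5, 3))
    pts = np.vstack([pts, pts])
    d = squareform(pdist(pts))
    labels = np.array(["a"] * 5 + ["b"] * 5)
    res = dv.dispersion_test(d, labels, n_perm=99, seed=0)
    assert res.f == pytest.approx(0.0, abs=1e-12)


def test_dispersion_null_calibration():
    rejections = []
    labels = np.array(["a"] * 9 + ["b"] * 9)
    for seed in range(200):
        rng = np.random.default_rng(seed + 10_000)
        pts = rng.standard_normal((18, 4))
        d = squareform(pdist(pts))
        res = dv.dispersion_test(d, labels, n_perm=99, seed=seed)
        rejections.append(res.p <= 0.05)
    assert 0.02 <= np.mean(rejections) <= 0.09


def test_centroid_comparison_extreme():
    dists = np.concatenate([np.arange(8.0), np.arange(10.0, 18.0)])
    labels = np.array(["a"] * 8 + ["b"] * 8)
    p = dv.centroid_distance_comparison(dists, labels)
    assert p == pytest.approx(2.0 / 12870.0)


def test_centroid_comparison_identical_groups():
    dists = np.concatenate([np.arange(6.0), np.arange(6.0)])
    labels = np.array(["a"] * 6 + ["b"] * 6)
    assert dv.centroid_distance_comparison(dists, labels) == 1.0


def test_synth_dispersion_directionality(default_study):
    """Planted tighter responders sit closer to their centroid."""
    d = dv.beta_diversity(
        default_study.abundance, "weighted_unifrac", tree=default_study.tree
    )
    labels = default_study.sample_meta["responder"].to_numpy()
    res = dv.dispersion_test(d, labels, n_perm=99, seed=0)
    assert (
        res.centroid_distances[labels].mean()
        < res.centroid_distances[~labels].mean()
    )
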