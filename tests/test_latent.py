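"""PCA retention (Horn/Kaiser), cluster model selection, subject cluster
volumes, cluster maps, t-SNE embedding."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phenomap import (
    cluster_latent,
    cluster_subject_volumes,
    fit_pca_with_retention,
    render_cluster_map,
    tsne_embed,
)
from phenomap.patches import plan_patches


def _rank3_data(seed, n=1000, d=20, noise=0.5):
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, 3))
    W = rng.standard_normal((3, d))
    return Z @ W + noise * rng.standard_normal((n, d))


def test_horn_recovers_planted_rank():
    model = fit_pca_with_retention(_rank3_data(0), seed=1)
    assert model.horn_k == 3
    assert model.n_retained == 3


def test_horn_on_pure_noise_retains_at_most_one():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        model = fit_pca_with_retention(rng.standard_normal((500, 15)), seed=seed + 100)
        assert model.horn_k <= 1


def test_kaiser_counts_correlation_eigenvalues_above_one():
    rng = np.random.default_rng(3)
    base = rng.standard_normal((400, 2))
    # two pairs of near-duplicate variables -> two correlation eigenvalues
    # near 2, the rest near 0
    X = np.column_stack([base[:, 0], base[:, 0], base[:, 1], base[:, 1]])
    X = X + 0.05 * rng.standard_normal(X.shape)
    model = fit_pca_with_retention(X, seed=0)
    assert model.kaiser_k == 2
    assert np.all(np.diff(model.eigenvalues) <= 1e-9)  # sorted descending


def test_pca_rejects_single_row():
    with pytest.raises(ValueError):
        fit_pca_with_retention(np.zeros((1, 4)))


def _blobs(seed, k=4, n_per=100, d=5, sep=12.0):
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((k, d)) * sep
    X = np.vstack([centers[i] + rng.standard_normal((n_per, d)) for i in range(k)])
    y = np.repeat(np.arange(k), n_per)
    return X, y


def test_cluster_selection_finds_four_blobs():
    X, y = _blobs(0)
    model = cluster_latent(X, k_range=range(2, 7), seed=1)
    assert model.k == 4
    assert adjusted_rand_score(y, model.assignments) >= 0.99
    assert set(model.assignments) == {1, 2, 3, 4}


def test_single_blob_has_weak_silhouette():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((300, 5))
    model = cluster_latent(X, k_range=range(2, 6), seed=3)
    assert model.selection["silhouette"].max() < 0.3


def test_cluster_determinism():
    X, _ = _blobs(4)
    a = cluster_latent(X, seed=7)
    b = cluster_latent(X, seed=7)
    assert a.method == b.method and a.k == b.k
    assert np.array_equal(a.assignments, b.assignments)


def _brute_silhouette(X, labels):
    from scipy.spatial.distance import cdist

    D = cdist(X, X)
    s = np.zeros(len(X))
    for i in range(len(X)):
        same = (labels == labels[i]) & (np.arange(len(X)) != i)
        if same.sum() == 0:
            s[i] = 0.0
            continue
        a = D[i, same].mean()
        b = min(D[i, labels == c].mean() for c in set(labels) if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return s.mean()


def _brute_davies_bouldin(X, labels):
    ks = sorted(set(labels))
    cents = np.array([X[labels == c].mean(axis=0) for c in ks])
    spread = np.array(
        [np.linalg.norm(X[labels == c] - cents[i], axis=1).mean() for i, c in enumerate(ks)]
    )
    db = 0.0
    for i in range(len(ks)):
        db += max(
            (spread[i] + spread[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in range(len(ks))
            if j != i
        )
    return db / len(ks)


def _brute_calinski_harabasz(X, labels):
    ks = sorted(set(labels))
    n, k = len(X), len(ks)
    mean = X.mean(axis=0)
    B = sum((labels == c).sum() * np.sum((X[labels == c].mean(axis=0) - mean) ** 2) for c in ks)
    W = sum(np.sum((X[labels == c] - X[labels == c].mean(axis=0)) ** 2) for c in ks)
    return (B / (k - 1)) / (W / (n - k))


def test_quality_metrics_match_brute_force():
    from sklearn.metrics import (
        calinski_harabasz_score,
        davies_bouldin_score,
        silhouette_score,
    )

    rng = np.random.default_rng(5)
    X = rng.standard_normal((150, 4))
    labels = rng.integers(0, 3, 150)
    assert silhouette_score(X, labels) == pytest.approx(_brute_silhouette(X, labels), abs=1e-9)
    assert davies_bouldin_score(X, labels) == pytest.approx(
        _brute_davies_bouldin(X, labels), abs=1e-9
    )
    assert calinski_harabasz_score(X, labels) == pytest.approx(
        _brute_calinski_harabasz(X, labels), abs=1e-9
    )


def test_subject_volumes_sum_to_one():
    meta = pd.DataFrame(
        {"subject_id": ["A"] * 4 + ["B"] * 3, "stage": ["GOLD1"] * 4 + ["GOLD2"] * 3}
    )
    assignments = np.array([2, 2, 2, 2, 1, 3, 3])
    vols = cluster_subject_volumes(assignments, meta, k=4)
    a = vols[vols["subject_id"] == "A"].iloc[0]
    assert [a[f"cluster_{i}"] for i in (1, 2, 3, 4)] == [0.0, 1.0, 0.0, 0.0]
    frac_cols = [c for c in vols.columns if c.startswith("cluster_")]
    assert np.allclose(vols[frac_cols].sum(axis=1), 1.0)
    b = vols[vols["subject_id"] == "B"].iloc[0]
    assert b["cluster_3"] == pytest.approx(2 / 3)


def test_cluster_map_blocks_and_frequencies():
    mask = np.ones((100, 50, 50), bool)
    grid = plan_patches(mask, patch_size=50, overlap_fraction=0.0, min_lung_fraction=0.0)
    labels = np.array([1, 2])
    vol = render_cluster_map(labels, grid, mask)
    assert (vol[:50] == 1).all() and (vol[50:] == 2).all()

    single = plan_patches(np.ones((50, 50, 50), bool))
    vol1 = render_cluster_map(np.array([3]), single, np.ones((50, 50, 50), bool))
    assert (vol1 == 3).all()


def test_cluster_map_tie_breaks_to_lowest_label():
    from phenomap.patches import PatchGrid

    mask = np.ones((21, 11, 11), bool)
    grid = PatchGrid(
        patch_size=11,
        effective_size=(11, 11, 11),
        overlap_fraction=0.0,
        origins=np.array([[0, 0, 0], [10, 0, 0]]),
        lung_fraction=np.ones(2),
        coverage=1.0,
        volume_shape=(21, 11, 11),
    )
    vol = render_cluster_map(np.array([4, 2]), grid, mask)
    # centers at x=5 and x=15; x=10 is equidistant -> lowest label wins
    assert (vol[:10] == 4).all() and (vol[11:] == 2).all()
    assert (vol[10] == 2).all()


def test_tsne_shapes_determinism_and_separation():
    rng = np.random.default_rng(6)
    a = rng.standard_normal((60, 10))
    b = rng.standard_normal((60, 10)) + 8.0
    fit = np.vstack([a[:40], b[:40]])
    test = np.vstack([a[40:], b[40:]])
    emb1, t1 = tsne_embed(fit, test, seed=3, perplexity=15)
    emb2, t2 = tsne_embed(fit, test, seed=3, perplexity=15)
    assert emb1.shape == (80, 2) and t1.shape == (40, 2)
    assert np.array_equal(emb1, emb2) and np.array_equal(t1, t2)
    lab = np.array([0] * 40 + [1] * 40)
    intra = np.linalg.norm(emb1[lab == 0] - emb1[lab == 0].mean(0), axis=1).mean()
    inter = np.linalg.norm(emb1[lab == 0].mean(0) - emb1[lab == 1].mean(0))
    assert inter > intra


def test_tsne_requires_fifty_rows():
    with pytest.raises(ValueError):
        tsne_embed(np.zeros((10, 3)))
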