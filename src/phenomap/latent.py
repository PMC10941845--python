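"""Latent-space structure: PCA with principled retention, clustering with
multi-metric model selection, per-subject cluster volumes, cluster maps,
and 2-D t-SNE visualization embeddings.

Component retention follows Horn's parallel analysis (observed
correlation-scale eigenvalues against a percentile of eigenvalues from
same-shape standard-normal data), with the Kaiser criterion reported
alongside.  Cluster model selection compares mini-batch K-means and
Gaussian mixtures over a range of k by rank-aggregating silhouette
(maximize), Davies-Bouldin (minimize) and Calinski-Harabasz (maximize).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import MiniBatchKMeans
from sklearn.manifold import TSNE
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .patches import PatchGrid


@dataclass
class PCAModel:
    """PCA with parallel-analysis retention evidence.

    Scores/loadings are computed on mean-centered (unscaled) features;
    Horn's parallel analysis and the Kaiser criterion are evaluated on the
    correlation scale, where the standard-normal surrogate eigenvalues are
    comparable.  ``n_retained = max(1, horn_k)``.
    """

    mean: np.ndarray
    components: np.ndarray  # (rank, d) rows = principal axes
    eigenvalues: np.ndarray  # covariance-scale, descending
    corr_eigenvalues: np.ndarray  # correlation-scale, descending
    pa_thresholds: np.ndarray  # parallel-analysis percentile curve
    horn_k: int
    kaiser_k: int
    n_retained: int
    variable_mask: np.ndarray  # columns with nonzero variance

    def transform(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        k = n_components or self.n_retained
        return (np.asarray(X, float) - self.mean) @ self.components[:k].T


def fit_pca_with_retention(
    X: np.ndarray,
    n_pa_reps: int = 100,
    pa_percentile: float = 95.0,
    seed: int = 0,
) -> PCAModel:
    """PCA plus Horn's parallel analysis / Kaiser retention.

    Horn retention counts leading components whose correlation-scale
    eigenvalue exceeds the ``pa_percentile`` of the matched eigenvalue from
    ``n_pa_reps`` standard-normal matrices of the same shape, stopping at
    the first failure.
    """
    X = np.asarray(X, float)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    # covariance-scale decomposition for scores/loadings
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = svals**2 / (n - 1)

    sd = Xc.std(axis=0, ddof=1)
    variable_mask = sd > 0
    d_eff = int(variable_mask.sum())
    if d_eff == 0:
        raise ValueError("all columns are constant")
    Z = Xc[:, variable_mask] / sd[variable_mask]
    corr_eigs = np.sort(np.linalg.svd(Z, compute_uv=False) ** 2 / (n - 1))[::-1]

    rng = np.random.default_rng(seed)
    null_eigs = np.empty((n_pa_reps, d_eff))
    for r in range(n_pa_reps):
        R = rng.standard_normal((n, d_eff))
        R = (R - R.mean(axis=0)) / R.std(axis=0, ddof=1)
        null_eigs[r] = np.sort(np.linalg.svd(R, compute_uv=False) ** 2 / (n - 1))[::-1]
    pa_thresholds = np.percentile(null_eigs, pa_percentile, axis=0)

    horn_k = 0
    for lam, thr in zip(corr_eigs, pa_thresholds):
        if lam > thr:
            horn_k += 1
        else:
            break
    kaiser_k = int((corr_eigs > 1.0).sum())
    return PCAModel(
        mean=mean,
        components=Vt,
        eigenvalues=eigenvalues,
        corr_eigenvalues=corr_eigs,
        pa_thresholds=pa_thresholds,
        horn_k=horn_k,
        kaiser_k=kaiser_k,
        n_retained=max(1, horn_k),
        variable_mask=variable_mask,
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    method: str
    k: int
    assignments: np.ndarray  # labels in 1..k
    quality: dict[str, float]
    selection: pd.DataFrame  # full (method, k) selection table
    seed: int


def _fit_one(method: str, k: int, S: np.ndarray, seed: int, minibatch_size: int) -> np.ndarray:
    if method == "minibatch_kmeans":
        km = MiniBatchKMeans(
            n_clusters=k,
            batch_size=minibatch_size,
            random_state=seed,
            n_init=3,
            max_iter=200,
        ).fit(S)
        return km.labels_
    if method == "gaussian_mixture":
        gm = GaussianMixture(
            n_components=k, covariance_type="full", random_state=seed, n_init=2, reg_covar=1e-6
        ).fit(S)
        return gm.predict(S)
    raise ValueError(f"unknown clustering method {method!r}")


def cluster_latent(
    S: np.ndarray,
    methods: tuple[str, ...] = ("minibatch_kmeans", "gaussian_mixture"),
    k_range: range | tuple[int, ...] = range(2, 9),
    seed: int = 0,
    minibatch_size: int = 1000,
    max_retries: int = 5,
) -> ClusterModel:
    """Fit every (method, k), score with silhouette/DB/CH, and select the
    lowest mean rank (ties -> smaller k, then method order)."""
    S = np.asarray(S, float)
    n = S.shape[0]
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("k_range empty after bounding to [2, n-1]")
    ss = np.random.SeedSequence(seed)
    rows = []
    labelings: dict[tuple[str, int], np.ndarray] = {}
    for mi, method in enumerate(methods):
        for k in k_range:
            labels = None
            for attempt in range(max_retries):
                sub_seed = int(
                    np.random.SeedSequence((seed, mi, k, attempt)).generate_state(1)[0] % (2**31)
                )
                cand = _fit_one(method, k, S, sub_seed, minibatch_size)
                if len(np.unique(cand)) == k:
                    labels = cand
                    break
            if labels is None:
                raise RuntimeError(f"degenerate clusters for {method}, k={k} after retries")
            labelings[(method, k)] = labels + 1
            rows.append(
                {
                    "method": method,
                    "k": k,
                    "silhouette": silhouette_score(S, labels),
                    "davies_bouldin": davies_bouldin_score(S, labels),
                    "calinski_harabasz": calinski_harabasz_score(S, labels),
                }
            )
    table = pd.DataFrame(rows)
    # rank-aggregate: silhouette and CH high is good, DB low is good
    table["rank_sil"] = rankdata(-table["silhouette"])
    table["rank_db"] = rankdata(table["davies_bouldin"])
    table["rank_ch"] = rankdata(-table["calinski_harabasz"])
    table["mean_rank"] = table[["rank_sil", "rank_db", "rank_ch"]].mean(axis=1)
    order = np.lexsort(
        (
            [list(methods).index(m) for m in table["method"]],
            table["k"].to_numpy(),
            table["mean_rank"].to_numpy(),
        )
    )
    best = table.iloc[order[0]]
    method, k = str(best["method"]), int(best["k"])
    quality = {
        "silhouette": float(best["silhouette"]),
        "davies_bouldin": float(best["davies_bouldin"]),
        "calinski_harabasz": float(best["calinski_harabasz"]),
    }
    return ClusterModel(
        method=method,
        k=k,
        assignments=labelings[(method, k)],
        quality=quality,
        selection=table,
        seed=seed,
    )


def cluster_subject_volumes(assignments: np.ndarray, meta: pd.DataFrame, k: int) -> pd.DataFrame:
    """Per-subject relative cluster volumes: fraction of the subject's
    patches in each cluster (columns cluster_1..cluster_k; rows sum to 1)."""
    if len(assignments) != len(meta):
        raise ValueError("assignments and metadata length mismatch")
    df = meta[["subject_id", "stage"]].copy()
    df["cluster"] = np.asarray(assignments, int)
    rows = []
    for sid, g in df.groupby("subject_id", sort=False):
        counts = np.bincount(g["cluster"].to_numpy(), minlength=k + 1)[1 : k + 1]
        fr = counts / counts.sum()
        row = {"subject_id": sid, "stage": g["stage"].iloc[0]}
        row.update({f"cluster_{c + 1}": fr[c] for c in range(k)})
        rows.append(row)
    return pd.DataFrame(rows)


def render_cluster_map(assignments: np.ndarray, grid: PatchGrid, mask: np.ndarray) -> np.ndarray:
    """Voxel labelmap: each lung voxel takes the label of the patch whose
    centre is nearest (ties -> lowest label); non-lung voxels are 0."""
    mask = np.asarray(mask, bool)
    labels = np.asarray(assignments, int)
    if len(labels) != len(grid.origins):
        raise ValueError("one label per patch required")
    centers = grid.origins + (np.asarray(grid.effective_size) - 1) / 2.0
    vox = np.argwhere(mask).astype(float)
    d2 = ((vox[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    dmin = d2.min(axis=1, keepdims=True)
    tie = d2 <= dmin + 1e-9
    cand = np.where(tie, labels[None, :], np.iinfo(np.int64).max)
    vox_labels = cand.min(axis=1)
    out = np.zeros(grid.volume_shape, dtype=np.int32)
    out[mask] = vox_labels
    return out


# ---------------------------------------------------------------------------
# t-SNE
# ---------------------------------------------------------------------------


def tsne_embed(
    fit_features: np.ndarray,
    transform_features: np.ndarray | None = None,
    seed: int = 0,
    perplexity: float = 30.0,
    n_neighbors_transform: int = 10,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Fit a 2-D t-SNE on the evaluation set and place test points into the
    fitted embedding by inverse-distance-weighted nearest-neighbour
    barycenters in feature space (visualization only)."""
    F = np.asarray(fit_features, float)
    if F.shape[0] < 50:
        raise ValueError("need at least 50 rows to fit the embedding")
    perp = min(perplexity, (F.shape[0] - 1) / 3.0)
    emb = TSNE(
        n_components=2,
        perplexity=perp,
        init="pca",
        random_state=seed,
        max_iter=500,
    ).fit_transform(F)
    if transform_features is None:
        return emb, None
    T = np.asarray(transform_features, float)
    nn = NearestNeighbors(n_neighbors=min(n_neighbors_transform, F.shape[0])).fit(F)
    dist, idx = nn.kneighbors(T)
    w = 1.0 / (dist + 1e-8)
    w /= w.sum(axis=1, keepdims=True)
    emb_t = np.einsum("ij,ijk->ik", w, emb[idx])
    return emb, emb_t
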