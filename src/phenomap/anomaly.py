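"""Density-based regional anomaly scoring.

A reference density is fitted to latent features of "normal" lung patches
(patches with <1% emphysema from subjects without airflow obstruction:
never-smoker controls and GOLD 0).  Every patch is then scored by the
negative log-likelihood (NLL, nats) under that reference; patient-level
scores aggregate the patch scores; anomaly map volumes are rendered by
averaging patch scores into voxels and min-max normalizing to the 5th/95th
percentiles of the cohort's patch-score distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .patches import LatentFeatures, PatchGrid

REFERENCE_STAGES = ("control", "GOLD0")


class EmptyReferenceError(ValueError):
    """No reference patches available; enlarge the cohort or relax filters."""


@dataclass
class ReferenceDensity:
    """Fitted reference distribution of normal-patch latent features.

    ``family`` is ``gaussian`` (single full-covariance Gaussian) or
    ``gaussian_mixture`` (full-covariance GMM, components chosen by minimum
    BIC over ``k_range``).  An optional PCA-whitening transform (kept with
    the density) reduces the feature space to at most ``whiten_dim``
    dimensions before fitting so covariance estimation stays well-posed.
    """

    family: str
    n_components: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: float
    bic: float
    bic_table: dict[int, float]
    n_train: int
    pca: PCA | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(X) if self.pca is not None else np.asarray(X, float)

    def nll(self, X: np.ndarray) -> np.ndarray:
        """Negative log-likelihood per row (in the fitted/whitened space)."""
        Z = self.transform(X)
        if Z.shape[1] != self.means.shape[1]:
            raise ValueError(
                f"feature dimension {Z.shape[1]} != density dimension {self.means.shape[1]}"
            )
        comp = np.stack(
            [
                np.atleast_1d(multivariate_normal.logpdf(Z, mean=m, cov=c, allow_singular=False))
                for m, c in zip(self.means, self.covariances)
            ],
            axis=1,
        ).reshape(len(Z), -1)
        logw = np.log(self.weights)[None, :]
        from scipy.special import logsumexp

        return -logsumexp(comp + logw, axis=1)


def select_reference_patches(
    features: LatentFeatures,
    reference_stages: Sequence[str] = REFERENCE_STAGES,
    emph_pct_threshold: float = 1.0,
) -> np.ndarray:
    """Boolean selector of reference patches: <``emph_pct_threshold``%
    emphysema (patch-level LAA-950 on inspiration) from subjects in
    ``reference_stages``."""
    meta = features.meta
    sel = meta["stage"].isin(reference_stages) & (meta["patch_emph_pct"] < emph_pct_threshold)
    sel = sel.to_numpy()
    if not sel.any():
        raise EmptyReferenceError(
            "no reference patches; use a larger cohort or relax the emphysema filter"
        )
    return sel


def fit_reference_density(
    X: np.ndarray,
    family: str = "gaussian_mixture",
    k_range: Iterable[int] = range(1, 9),
    seed: int = 0,
    whiten_dim: int | None = 32,
    reg_covar: float = 1e-6,
) -> ReferenceDensity:
    """Fit the reference density, optionally after PCA whitening."""
    X = np.asarray(X, float)
    n = X.shape[0]
    pca = None
    Z = X
    if whiten_dim is not None:
        n_comp = min(whiten_dim, n - 1, X.shape[1])
        pca = PCA(n_components=n_comp, whiten=True, random_state=seed)
        pca.fit(X)
        # drop numerically dead directions (zero-variance padded columns)
        keep = pca.explained_variance_ > 1e-10
        pca.components_ = pca.components_[keep]
        pca.explained_variance_ = pca.explained_variance_[keep]
        pca.explained_variance_ratio_ = pca.explained_variance_ratio_[keep]
        pca.singular_values_ = pca.singular_values_[keep]
        pca.n_components_ = int(keep.sum())
        Z = pca.transform(X)
    d = Z.shape[1]
    if n <= d:
        raise ValueError(f"need more reference samples ({n}) than dimensions ({d})")

    if family == "gaussian":
        mean = Z.mean(axis=0)
        cov = np.cov(Z, rowvar=False) + reg_covar * np.eye(d)
        ll = float(multivariate_normal.logpdf(Z, mean=mean, cov=cov).sum())
        n_params = d + d * (d + 1) / 2
        bic = -2 * ll + n_params * np.log(n)
        return ReferenceDensity(
            family="gaussian",
            n_components=1,
            weights=np.array([1.0]),
            means=mean[None, :],
            covariances=cov[None, :, :],
            log_likelihood=ll,
            bic=bic,
            bic_table={1: bic},
            n_train=n,
            pca=pca,
        )
    if family != "gaussian_mixture":
        raise ValueError(f"unknown density family {family!r}")

    bic_table: dict[int, float] = {}
    best = None
    for k in k_range:
        if k >= n:
            continue
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=reg_covar,
            random_state=seed,
            n_init=2,
            max_iter=300,
        ).fit(Z)
        bic_table[k] = float(gm.bic(Z))
        if best is None or bic_table[k] < bic_table[best[0]]:
            best = (k, gm)
    if best is None:
        raise ValueError("empty k_range")
    k, gm = best
    return ReferenceDensity(
        family="gaussian_mixture",
        n_components=k,
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        log_likelihood=float(gm.score(Z) * n),
        bic=bic_table[k],
        bic_table=bic_table,
        n_train=n,
        pca=pca,
    )


def score_patches(density: ReferenceDensity, features: LatentFeatures | np.ndarray) -> np.ndarray:
    """Per-patch anomaly scores: NLL under the reference density (larger =
    more anomalous)."""
    X = features.matrix if isinstance(features, LatentFeatures) else np.asarray(features, float)
    return density.nll(X)


def aggregate_patient_score(patch_scores: np.ndarray, method: str = "mean") -> float:
    scores = np.asarray(patch_scores, float)
    if scores.size == 0:
        raise ValueError("no patch scores to aggregate")
    if method == "mean":
        return float(scores.mean())
    if method == "median":
        return float(np.median(scores))
    if method == "max":
        return float(scores.max())
    raise ValueError(f"unknown aggregation method {method!r}")


def render_anomaly_map(
    patch_scores: np.ndarray,
    grid: PatchGrid,
    mask: np.ndarray,
    bounds: tuple[float, float],
) -> np.ndarray:
    """Normalized anomaly map volume in [0, 1].

    Each lung voxel's raw value is the mean score of all patches containing
    it; values are min-max normalized to ``bounds`` = (p5, p95) of the
    cohort patch-score distribution and clipped; non-lung voxels are 0.
    """
    mask = np.asarray(mask, bool)
    p5, p95 = bounds
    acc = np.zeros(grid.volume_shape, float)
    cnt = np.zeros(grid.volume_shape, float)
    sx, sy, sz = grid.effective_size
    for score, o in zip(patch_scores, grid.origins):
        sl = (slice(o[0], o[0] + sx), slice(o[1], o[1] + sy), slice(o[2], o[2] + sz))
        acc[sl] += score
        cnt[sl] += 1.0
    if p95 <= p5:
        warnings.warn("degenerate normalization bounds (p95 <= p5); map set to 0")
        return np.zeros(grid.volume_shape, float)
    with np.errstate(invalid="ignore"):
        raw = np.where(cnt > 0, acc / np.maximum(cnt, 1.0), 0.0)
    out = np.clip((raw - p5) / (p95 - p5), 0.0, 1.0)
    out[~mask] = 0.0
    out[cnt == 0] = 0.0
    return out


def score_cohort(
    features: LatentFeatures,
    density: ReferenceDensity,
    aggregation: str = "mean",
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> tuple[pd.DataFrame, np.ndarray, tuple[float, float]]:
    """Score every patch, aggregate per subject, and compute cohort-wide
    normalization bounds.  Returns (patient table, patch scores, bounds)."""
    patch_scores = score_patches(density, features)
    bounds = tuple(np.percentile(patch_scores, percentiles))
    meta = features.meta.copy()
    meta["score"] = patch_scores
    rows = []
    for sid, g in meta.groupby("subject_id", sort=False):
        rows.append(
            {
                "subject_id": sid,
                "stage": g["stage"].iloc[0],
                "site_id": g["site_id"].iloc[0],
                "n_patches": len(g),
                "patient_score": aggregate_patient_score(g["score"].to_numpy(), aggregation),
            }
        )
    return pd.DataFrame(rows), patch_scores, bounds
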