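"""Overlapping 3D patch extraction and per-patch featurization.

Patches are cubic regions of interest (default 50 voxels per side) tiled
with 20% overlap (stride = 0.8 x size, final tile clamped to the volume
edge).  Patches with too little lung are dropped.  The default featurizer
is a deterministic paired-HU-histogram descriptor; a small contrastive
encoder (:mod:`phenomap.contrastive`) can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .synthetic import Cohort, DimensionError, PairedCTStudy


@dataclass
class PatchGrid:
    """Planned patch tiling for one volume."""

    patch_size: int
    effective_size: tuple[int, int, int]
    overlap_fraction: float
    origins: np.ndarray  # (n, 3) integer corners
    lung_fraction: np.ndarray  # (n,)
    coverage: float
    volume_shape: tuple[int, int, int]


@dataclass
class LatentFeatures:
    """Per-patch feature matrix with patch geometry metadata."""

    matrix: np.ndarray  # (n_patches, d)
    meta: pd.DataFrame  # subject_id, origin_{x,y,z}, lung_fraction, ...
    featurizer_id: str

    def __post_init__(self) -> None:
        if len(self.meta) != self.matrix.shape[0]:
            raise ValueError("metadata rows != feature rows")
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite feature entries")


def _axis_positions(dim: int, size: int, stride: int) -> list[int]:
    pos = list(range(0, dim - size + 1, stride))
    if pos[-1] != dim - size:
        pos.append(dim - size)
    return pos


def plan_patches(
    mask: np.ndarray,
    patch_size: int = 50,
    overlap_fraction: float = 0.2,
    min_lung_fraction: float = 0.2,
    clamp: bool = True,
) -> PatchGrid:
    """Plan overlapping patch origins over a lung mask.

    Origins run 0, stride, 2*stride, ... per axis with the final origin
    clamped so the last patch ends at the volume edge.  With ``clamp`` the
    patch side is shrunk on axes shorter than ``patch_size``; otherwise a
    short axis is a :class:`DimensionError`.
    """
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape
    eff = []
    for dim in shape:
        if dim < patch_size:
            if not clamp:
                raise DimensionError(
                    f"dimension {dim} < patch size {patch_size} and clamping disabled"
                )
            eff.append(dim)
        else:
            eff.append(patch_size)
    stride = max(1, round(patch_size * (1.0 - overlap_fraction)))
    axes_pos = [_axis_positions(dim, s, stride) for dim, s in zip(shape, eff)]
    origins = np.array(
        [(x, y, z) for x in axes_pos[0] for y in axes_pos[1] for z in axes_pos[2]],
        dtype=int,
    )
    eff_t = tuple(eff)
    n_patch_vox = int(np.prod(eff_t))
    lung_fraction = np.array(
        [
            mask[o[0] : o[0] + eff_t[0], o[1] : o[1] + eff_t[1], o[2] : o[2] + eff_t[2]].sum()
            / n_patch_vox
            for o in origins
        ]
    )
    keep = lung_fraction >= min_lung_fraction
    origins, lung_fraction = origins[keep], lung_fraction[keep]
    covered = np.zeros(shape, dtype=bool)
    for o in origins:
        covered[o[0] : o[0] + eff_t[0], o[1] : o[1] + eff_t[1], o[2] : o[2] + eff_t[2]] = True
    n_lung = int(mask.sum())
    coverage = float((covered & mask).sum() / n_lung) if n_lung else 0.0
    return PatchGrid(
        patch_size=patch_size,
        effective_size=eff_t,
        overlap_fraction=overlap_fraction,
        origins=origins,
        lung_fraction=lung_fraction,
        coverage=coverage,
        volume_shape=tuple(shape),
    )


def extract_patch_pairs(
    study: PairedCTStudy, grid: PatchGrid
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Crop the (insp, exp, mask) sub-grids for every planned origin."""
    if grid.volume_shape != study.insp.shape:
        raise ValueError("grid was planned on a different volume shape")
    sx, sy, sz = grid.effective_size
    out = []
    for o in grid.origins:
        x, y, z = (int(v) for v in o)
        if x + sx > study.insp.shape[0] or y + sy > study.insp.shape[1] or z + sz > study.insp.shape[2]:
            raise ValueError(f"origin {o} out of bounds")
        sl = (slice(x, x + sx), slice(y, y + sy), slice(z, z + sz))
        out.append((study.insp[sl], study.exp_registered[sl], study.lung_mask[sl]))
    return out


# ---------------------------------------------------------------------------
# Featurizers
# ---------------------------------------------------------------------------

HU_RANGE_DEFAULT = (-1024.0, -400.0)


def featurize_histogram(
    insp_patch: np.ndarray,
    exp_patch: np.ndarray,
    mask_patch: np.ndarray,
    n_bins: int = 64,
    hu_range: tuple[float, float] = HU_RANGE_DEFAULT,
    dim: int = 512,
) -> np.ndarray:
    """Deterministic per-patch descriptor: lung-voxel HU histograms of the
    inspiratory and expiratory crops (probability mass per bin), their
    means/SDs (scaled by 1/1000) and the patch-level LAA-950/LAA-856
    fractions, zero-padded (or truncated) to ``dim``."""
    m = np.asarray(mask_patch, bool)
    if not m.any():
        raise ValueError("patch contains no lung voxels")
    vi = np.clip(np.asarray(insp_patch, float)[m], hu_range[0], hu_range[1] - 1e-6)
    ve = np.clip(np.asarray(exp_patch, float)[m], hu_range[0], hu_range[1] - 1e-6)
    hist_i, _ = np.histogram(vi, bins=n_bins, range=hu_range)
    hist_e, _ = np.histogram(ve, bins=n_bins, range=hu_range)
    hist_i = hist_i / len(vi)
    hist_e = hist_e / len(ve)
    stats = np.array(
        [
            vi.mean() / 1000.0,
            vi.std() / 1000.0,
            ve.mean() / 1000.0,
            ve.std() / 1000.0,
            float((vi < -950.0).mean()),
            float((ve < -856.0).mean()),
        ]
    )
    feat = np.concatenate([hist_i, hist_e, stats])
    if len(feat) < dim:
        feat = np.pad(feat, (0, dim - len(feat)))
    return feat[:dim]


def _patch_laa(insp_patch, exp_patch, mask_patch) -> tuple[float, float]:
    m = np.asarray(mask_patch, bool)
    vi = np.asarray(insp_patch, float)[m]
    ve = np.asarray(exp_patch, float)[m]
    return float((vi < -950.0).mean()) * 100.0, float((ve < -856.0).mean()) * 100.0


def embed_study(
    study: PairedCTStudy,
    grid: PatchGrid,
    featurizer: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    featurizer_id: str,
) -> LatentFeatures:
    """Featurize every kept patch of one subject."""
    rows, feats = [], []
    for o, (pi, pe, pm) in zip(grid.origins, extract_patch_pairs(study, grid)):
        laa950, laa856 = _patch_laa(pi, pe, pm)
        feats.append(featurizer(pi, pe, pm))
        rows.append(
            {
                "subject_id": study.subject_id,
                "stage": study.stage,
                "site_id": study.site_id,
                "origin_x": int(o[0]),
                "origin_y": int(o[1]),
                "origin_z": int(o[2]),
                "lung_fraction": float(grid.lung_fraction[len(feats) - 1]),
                "patch_emph_pct": laa950,
                "patch_airtrap_pct": laa856,
            }
        )
    mat = np.vstack(feats) if feats else np.empty((0, 0))
    return LatentFeatures(matrix=mat, meta=pd.DataFrame(rows), featurizer_id=featurizer_id)


def embed_cohort(
    cohort: Cohort,
    featurizer: Callable[..., np.ndarray] | None = None,
    featurizer_id: str = "histogram",
    patch_size: int = 50,
    overlap_fraction: float = 0.2,
    min_lung_fraction: float = 0.2,
    feature_dim: int = 512,
) -> LatentFeatures:
    """Plan, extract and featurize patches for a whole cohort; one stacked
    feature matrix with per-patch metadata (subject, stage, origin, lung
    fraction, patch-level emphysema/air-trapping percentages)."""
    if featurizer is None:
        featurizer = lambda pi, pe, pm: featurize_histogram(pi, pe, pm, dim=feature_dim)
    parts = []
    grid_cache: dict[tuple, PatchGrid] = {}
    for s in cohort.subjects:
        key = s.study.insp.shape
        if key not in grid_cache:
            grid_cache[key] = plan_patches(
                s.study.lung_mask, patch_size, overlap_fraction, min_lung_fraction
            )
        # masks are identical across synthetic subjects of one shape; replan
        # defensively if they are not
        grid = grid_cache[key]
        parts.append(embed_study(s.study, grid, featurizer, featurizer_id))
    matrix = np.vstack([p.matrix for p in parts])
    meta = pd.concat([p.meta for p in parts], ignore_index=True)
    return LatentFeatures(matrix=matrix, meta=meta, featurizer_id=featurizer_id)
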