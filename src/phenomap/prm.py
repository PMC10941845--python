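"""Parametric response mapping (PRM) of paired inspiratory/expiratory CT.

Joint voxel-wise HU thresholding classifies lung parenchyma into Normal,
functional small-airway disease (fSAD) and Emphysema; voxels outside all
three HU boxes (airways, vessels, dense tissue) are Excluded.  Boundary
closure convention: -950 HU on inspiration belongs to the emphysema box,
-856 HU on expiration belongs to the normal box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import PairedCTStudy

#: Integer label codes used in PRM labelmaps.
PRM_BACKGROUND, PRM_NORMAL, PRM_FSAD, PRM_EMPH, PRM_EXCLUDED = 0, 1, 2, 3, 4

PRM_CODE_MEANING = {
    PRM_BACKGROUND: "background",
    PRM_NORMAL: "Normal",
    PRM_FSAD: "fSAD",
    PRM_EMPH: "Emph",
    PRM_EXCLUDED: "Excluded",
}


class AlignmentError(ValueError):
    """Paired grids do not share a common shape."""


@dataclass
class PRMResult:
    """Voxel labelmap plus relative class volumes and LAA metrics.

    ``pct_normal/pct_fsad/pct_emph`` are percentages of PRM-*classified*
    lung voxels (they sum to 100); ``pct_excluded`` is relative to all lung
    voxels.  ``laa950_pct``/``laa856_pct`` are the classic low-attenuation
    percentages of lung voxels below -950 HU (inspiration) / -856 HU
    (expiration).
    """

    labelmap: np.ndarray
    pct_normal: float
    pct_fsad: float
    pct_emph: float
    pct_excluded: float
    laa950_pct: float
    laa856_pct: float


def classify_voxels(insp_hu: np.ndarray, exp_hu: np.ndarray) -> np.ndarray:
    """Classify paired HU values into PRM classes (vectorized).

    Emph:   insp in [-1000, -950]  and exp in [-1000, -856)
    fSAD:   insp in (-950, -810]   and exp in [-1000, -856)
    Normal: insp in (-950, -810]   and exp in [-856, -500]
    everything else: Excluded.
    """
    insp = np.asarray(insp_hu, dtype=float)
    exp = np.asarray(exp_hu, dtype=float)
    if insp.shape != exp.shape:
        raise AlignmentError(f"shape mismatch {insp.shape} vs {exp.shape}")
    if not (np.isfinite(insp).all() and np.isfinite(exp).all()):
        raise ValueError("non-finite HU values")

    out = np.full(insp.shape, PRM_EXCLUDED, dtype=np.uint8)
    insp_emph = (insp >= -1000.0) & (insp <= -950.0)
    insp_soft = (insp > -950.0) & (insp <= -810.0)
    exp_trap = (exp >= -1000.0) & (exp < -856.0)
    exp_norm = (exp >= -856.0) & (exp <= -500.0)
    out[insp_emph & exp_trap] = PRM_EMPH
    out[insp_soft & exp_trap] = PRM_FSAD
    out[insp_soft & exp_norm] = PRM_NORMAL
    return out


def laa_percent(hu: np.ndarray, mask: np.ndarray, threshold_hu: float) -> float:
    """Percentage of masked voxels strictly below ``threshold_hu``."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    return 100.0 * float((np.asarray(hu)[mask] < threshold_hu).sum()) / n


def compute_prm(study: PairedCTStudy) -> PRMResult:
    """Apply PRM to one subject; non-lung voxels stay background."""
    insp, exp, mask = study.insp, study.exp_registered, np.asarray(study.lung_mask, bool)
    if insp.shape != exp.shape or insp.shape != mask.shape:
        raise AlignmentError("insp/exp/mask shapes differ")
    n_lung = int(mask.sum())
    if n_lung == 0:
        raise ValueError("empty lung mask")

    labelmap = np.zeros(insp.shape, dtype=np.uint8)
    labelmap[mask] = classify_voxels(insp[mask], exp[mask])

    counts = {c: int((labelmap[mask] == c).sum()) for c in (PRM_NORMAL, PRM_FSAD, PRM_EMPH, PRM_EXCLUDED)}
    n_classified = counts[PRM_NORMAL] + counts[PRM_FSAD] + counts[PRM_EMPH]
    if n_classified == 0:
        pct_normal = pct_fsad = pct_emph = 0.0
    else:
        pct_normal = 100.0 * counts[PRM_NORMAL] / n_classified
        pct_fsad = 100.0 * counts[PRM_FSAD] / n_classified
        pct_emph = 100.0 * counts[PRM_EMPH] / n_classified
    return PRMResult(
        labelmap=labelmap,
        pct_normal=pct_normal,
        pct_fsad=pct_fsad,
        pct_emph=pct_emph,
        pct_excluded=100.0 * counts[PRM_EXCLUDED] / n_lung,
        laa950_pct=laa_percent(insp, mask, -950.0),
        laa856_pct=laa_percent(exp, mask, -856.0),
    )
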