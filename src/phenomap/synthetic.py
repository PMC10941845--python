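"""Synthetic paired-CT COPD cohort generator.

Emulates the statistical structure of a multi-site inspiratory/expiratory
CT study of never-smoker controls and GOLD 0-4 COPD patients: per-stage
emphysema and functional small-airway disease (fSAD) lesion burdens,
Hounsfield-unit distributions that land each tissue class in its intended
parametric-response-mapping (PRM) box, clinical covariates linearly linked
to lesion burden, and a random study-site intercept.

The expiratory volume is emitted on the same grid as the inspiratory one,
i.e. pre-registered; deformable registration is out of scope.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

#: Ordered disease stages: never-smoker controls, then GOLD 0-4.
STAGES: tuple[str, ...] = ("control", "GOLD0", "GOLD1", "GOLD2", "GOLD3", "GOLD4")
STAGE_ORDER: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Tissue label codes used in ground-truth labelmaps.
TISSUE_BACKGROUND, TISSUE_NORMAL, TISSUE_EMPH, TISSUE_FSAD = 0, 1, 2, 3


class ConfigurationError(ValueError):
    """Invalid generator configuration (impossible burden, bad bounds...)."""


class DimensionError(ValueError):
    """Grid too small for the requested patch/lesion geometry."""


@dataclass(frozen=True)
class HUModel:
    """Truncated-normal HU model for one tissue class in one breathing phase."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


# HU models chosen so that each tissue class falls deterministically inside
# its PRM interval: emphysema (insp < -950, exp < -856), fSAD (insp in
# (-950,-810], exp < -856), normal (insp in (-950,-810], exp in [-856,-500]).
DEFAULT_HU_MODELS: dict[str, dict[str, HUModel]] = {
    "normal": {
        "insp": HUModel(-870.0, 25.0, -949.5, -810.5),
        "exp": HUModel(-740.0, 35.0, -855.5, -500.5),
    },
    "emphysema": {
        "insp": HUModel(-975.0, 12.0, -999.5, -950.5),
        "exp": HUModel(-945.0, 20.0, -999.5, -856.5),
    },
    "fsad": {
        "insp": HUModel(-890.0, 25.0, -949.5, -810.5),
        "exp": HUModel(-915.0, 20.0, -999.5, -856.5),
    },
}

# Per-stage mean lesion fractions (emphysema, fSAD); multi-site COPD cohort
# class means divided by 100.
DEFAULT_STAGE_BURDEN_MEANS: dict[str, tuple[float, float]] = {
    "control": (0.003, 0.071),
    "GOLD0": (0.009, 0.147),
    "GOLD1": (0.026, 0.220),
    "GOLD2": (0.068, 0.289),
    "GOLD3": (0.133, 0.394),
    "GOLD4": (0.295, 0.451),
}


@dataclass(frozen=True)
class ClinicalCoeff:
    """Linear model for one clinical variable: intercept + c_emph*emph +
    c_fsad*fsad + site intercept + N(0, noise_sd), clipped to [lo, hi].

    ``site_scale`` scales the cohort-level site-intercept SD for this
    variable so one relative ``site_sd`` knob drives all variables.
    """

    intercept: float
    c_emph: float
    c_fsad: float
    noise_sd: float
    lo: float
    hi: float
    site_scale: float = 0.0


DEFAULT_CLINICAL_COEFFS: dict[str, ClinicalCoeff] = {
    # % predicted FEV1: falls steeply with emphysema, moderately with fSAD.
    "FEV1pp": ClinicalCoeff(98.0, -160.0, -70.0, 8.0, 5.0, 150.0, 1.0),
    "FEV1_FVC": ClinicalCoeff(0.80, -0.90, -0.45, 0.04, 0.05, 0.99, 0.005),
    # Functional residual capacity rises with air trapping (litres).
    "FRC": ClinicalCoeff(2.6, 3.5, 3.8, 0.40, 1.0, 9.0, 0.05),
    # Inspiratory reserve above FRC; TLC = FRC + this (keeps TLC >= FRC).
    "TLC_minus_FRC": ClinicalCoeff(2.8, -1.5, -1.2, 0.35, 0.3, 6.0, 0.04),
    "BODE": ClinicalCoeff(0.0, 11.0, 7.0, 0.8, 0.0, 10.0, 0.10),
    "SGRQ": ClinicalCoeff(4.0, 110.0, 75.0, 8.0, 0.0, 100.0, 1.0),
    "sixMWT": ClinicalCoeff(530.0, -550.0, -330.0, 55.0, 50.0, 900.0, 7.0),
    # Years smoked; controls are forced to zero downstream.
    "smoking_duration": ClinicalCoeff(30.0, 20.0, 18.0, 8.0, 5.0, 60.0, 1.0),
    "age": ClinicalCoeff(61.0, 0.0, 0.0, 8.0, 45.0, 80.0, 0.5),
    "BMI": ClinicalCoeff(28.0, -6.0, 0.0, 4.5, 16.0, 45.0, 0.3),
}


@dataclass
class CohortConfig:
    """Configuration of the synthetic paired-CT cohort."""

    n_per_stage: int = 10
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    stage_burden_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_BURDEN_MEANS)
    )
    burden_concentration: float = 30.0
    hu_models: dict[str, dict[str, HUModel]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_HU_MODELS.items()}
    )
    clinical_coeffs: dict[str, ClinicalCoeff] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_COEFFS)
    )
    n_sites: int = 4
    site_sd: float = 3.0
    lesion_radius_range: tuple[float, float] = (3.0, 7.0)
    seed: int = 0

    def validate(self, require_patchable: bool = False, patch_size: int = 50) -> None:
        if self.n_per_stage < 1:
            raise ConfigurationError("n_per_stage must be >= 1")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        prev_e, prev_f = -1.0, -1.0
        for stage in STAGES:
            e, f = self.stage_burden_means[stage]
            if not (0.0 <= e <= 1.0 and 0.0 <= f <= 1.0):
                raise ConfigurationError(f"burden means for {stage} outside [0,1]")
            if e < prev_e or f < prev_f:
                raise ConfigurationError(
                    "stage_burden_means must be monotone nondecreasing over stages"
                )
            prev_e, prev_f = e, f
        for cls, phases in self.hu_models.items():
            for phase, m in phases.items():
                for v in (m.mean, m.lo, m.hi):
                    if not (-1024.0 <= v <= 100.0):
                        raise ConfigurationError(
                            f"HU parameter {v} for {cls}/{phase} outside [-1024, 100]"
                        )
                if not m.lo < m.hi:
                    raise ConfigurationError(f"empty truncation interval for {cls}/{phase}")
        if require_patchable and any(d < patch_size for d in self.grid_shape):
            raise DimensionError(
                f"grid {self.grid_shape} cannot host a {patch_size}^3 patch"
            )


@dataclass
class PairedCTStudy:
    """One subject's paired CT data: inspiratory and registered expiratory
    HU grids plus a binary lung mask, all voxelwise aligned."""

    subject_id: str
    insp: np.ndarray
    exp_registered: np.ndarray
    lung_mask: np.ndarray
    stage: str
    site_id: int
    voxel_spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)

    def __post_init__(self) -> None:
        if not (self.insp.shape == self.exp_registered.shape == self.lung_mask.shape):
            raise ValueError("insp, exp_registered and lung_mask must share shape")
        if not self.lung_mask.any():
            raise ValueError("lung_mask is empty")


@dataclass
class GroundTruth:
    """Voxel-level tissue truth and the implied lesion fractions."""

    tissue_labelmap: np.ndarray
    emph_fraction: float
    fsad_fraction: float


@dataclass
class ClinicalRecord:
    subject_id: str
    FEV1pp: float
    FEV1_FVC: float
    FRC: float
    TLC: float
    FRC_TLC: float
    BODE: float
    SGRQ: float
    sixMWT: float
    smoking_duration: float
    smoking_status: int
    age: float
    sex: str
    BMI: float


@dataclass
class SubjectBundle:
    study: PairedCTStudy
    truth: GroundTruth
    clinical: ClinicalRecord


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectBundle]

    def clinical_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = dataclasses.asdict(s.clinical)
            row["stage"] = s.study.stage
            row["site_id"] = s.study.site_id
            rows.append(row)
        return pd.DataFrame(rows)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.study.subject_id for s in self.subjects],
                "stage": [s.study.stage for s in self.subjects],
                "emph_fraction": [s.truth.emph_fraction for s in self.subjects],
                "fsad_fraction": [s.truth.fsad_fraction for s in self.subjects],
            }
        )


def _ellipsoid(shape: Sequence[int], center: Sequence[float], semi: Sequence[float]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in shape)]
    acc = np.zeros(tuple(shape), dtype=float)
    for g, c, a in zip(grids, center, semi):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_lung_mask(shape: Sequence[int]) -> np.ndarray:
    """Two-ellipsoid (left/right lung) binary mask, axis order (x, y, z)."""
    nx, ny, nz = shape
    semi = (0.22 * nx, 0.42 * ny, 0.44 * nz)
    left = _ellipsoid(shape, (0.26 * nx, 0.5 * ny, 0.5 * nz), semi)
    right = _ellipsoid(shape, (0.74 * nx, 0.5 * ny, 0.5 * nz), semi)
    return left | right


def _place_lesions(
    labels: np.ndarray,
    lung_idx: np.ndarray,
    target_count: int,
    code: int,
    radius_range: tuple[float, float],
    rng: np.random.Generator,
    max_iter: int = 20000,
) -> None:
    """Grow spherical blobs of ``code`` on still-normal lung voxels until
    exactly ``target_count`` voxels carry the label (the last blob is trimmed
    by distance from its centre so the target is hit exactly)."""
    if target_count <= 0:
        return
    shape = labels.shape
    placed = 0
    for _ in range(max_iter):
        if placed >= target_count:
            return
        c = lung_idx[rng.integers(len(lung_idx))]
        r = rng.uniform(*radius_range)
        lo = np.maximum(c - int(np.ceil(r)), 0)
        hi = np.minimum(c + int(np.ceil(r)) + 1, shape)
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        gx, gy, gz = np.ogrid[box]
        d2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        sphere = d2 <= r * r
        sub = labels[box]
        new = sphere & (sub == TISSUE_NORMAL)
        n_new = int(new.sum())
        if n_new == 0:
            continue
        need = target_count - placed
        if n_new > need:
            # trim: keep the voxels closest to the blob centre
            dvals = np.where(new, d2, np.inf)
            flat = np.argsort(dvals, axis=None, kind="stable")[:need]
            keep = np.zeros(sub.shape, dtype=bool)
            keep.flat[flat] = True
            new = keep
            n_new = need
        sub[new] = code
        placed += n_new
    raise ConfigurationError(
        f"could not place {target_count} lesion voxels after {max_iter} blobs"
    )


def _beta_draw(mean: float, concentration: float, rng: np.random.Generator) -> float:
    if mean <= 0.0:
        return 0.0
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return float(rng.beta(a, b))


def _site_effects(config: CohortConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One random intercept per (site, clinical variable); SD = site_sd *
    per-variable site_scale."""
    return {
        name: rng.normal(0.0, config.site_sd * coeff.site_scale, size=config.n_sites)
        for name, coeff in config.clinical_coeffs.items()
    }


def _clinical_value(
    coeff: ClinicalCoeff, emph: float, fsad: float, site_effect: float, rng: np.random.Generator
) -> float:
    raw = (
        coeff.intercept
        + coeff.c_emph * emph
        + coeff.c_fsad * fsad
        + site_effect
        + rng.normal(0.0, coeff.noise_sd)
    )
    return float(np.clip(raw, coeff.lo, coeff.hi))


def generate_subject(
    stage: str,
    config: CohortConfig,
    rng: np.random.Generator,
    subject_id: str = "S000",
    site_id: int = 0,
    site_effects: dict[str, np.ndarray] | None = None,
) -> tuple[PairedCTStudy, GroundTruth, ClinicalRecord]:
    """Generate one subject: paired HU grids, lung mask, voxel truth, and a
    clinical record linearly linked to the lesion burdens.

    Deterministic given (stage, config, rng state).
    """
    if stage not in STAGE_ORDER:
        raise ConfigurationError(f"unknown stage {stage!r}")
    config.validate()
    shape = tuple(config.grid_shape)
    mask = make_lung_mask(shape)
    lung_idx = np.argwhere(mask)
    n_lung = len(lung_idx)

    mean_e, mean_f = config.stage_burden_means[stage]
    target_e = _beta_draw(mean_e, config.burden_concentration, rng)
    target_f = _beta_draw(mean_f, config.burden_concentration, rng)
    if target_e > 0.95 or target_f > 0.95:
        raise ConfigurationError(f"lesion burden target exceeds 0.95 ({target_e:.3f}, {target_f:.3f})")
    total = target_e + target_f
    if total > 0.95:
        # jointly unlucky draw: cap total lesional lung at 95%, preserving
        # the emphysema/fSAD ratio
        target_e *= 0.95 / total
        target_f *= 0.95 / total

    labels = np.zeros(shape, dtype=np.uint8)
    labels[mask] = TISSUE_NORMAL
    n_e = int(round(target_e * n_lung))
    n_f = int(round(target_f * n_lung))
    _place_lesions(labels, lung_idx, n_e, TISSUE_EMPH, config.lesion_radius_range, rng)
    _place_lesions(labels, lung_idx, n_f, TISSUE_FSAD, config.lesion_radius_range, rng)

    emph_fraction = float((labels == TISSUE_EMPH).sum() / n_lung)
    fsad_fraction = float((labels == TISSUE_FSAD).sum() / n_lung)

    insp = rng.normal(40.0, 15.0, size=shape).astype(np.float32)
    exp = rng.normal(40.0, 15.0, size=shape).astype(np.float32)
    for cls, code in (("normal", TISSUE_NORMAL), ("emphysema", TISSUE_EMPH), ("fsad", TISSUE_FSAD)):
        sel = labels == code
        n = int(sel.sum())
        if n == 0:
            continue
        insp[sel] = config.hu_models[cls]["insp"].sample(n, rng)
        exp[sel] = config.hu_models[cls]["exp"].sample(n, rng)

    study = PairedCTStudy(
        subject_id=subject_id,
        insp=insp,
        exp_registered=exp,
        lung_mask=mask,
        stage=stage,
        site_id=site_id,
        voxel_spacing_mm=tuple(config.voxel_spacing_mm),
    )
    truth = GroundTruth(labels, emph_fraction, fsad_fraction)

    if site_effects is None:
        site_effects = {name: np.zeros(config.n_sites) for name in config.clinical_coeffs}
    cc = config.clinical_coeffs
    val = {
        name: _clinical_value(cc[name], emph_fraction, fsad_fraction, site_effects[name][site_id], rng)
        for name in cc
    }
    frc = val["FRC"]
    tlc = frc + val["TLC_minus_FRC"]
    if stage == "control":
        smoking_duration, smoking_status = 0.0, 0
    else:
        smoking_duration = val["smoking_duration"]
        smoking_status = int(rng.integers(1, 3))
    clinical = ClinicalRecord(
        subject_id=subject_id,
        FEV1pp=val["FEV1pp"],
        FEV1_FVC=val["FEV1_FVC"],
        FRC=frc,
        TLC=tlc,
        FRC_TLC=frc / tlc,
        BODE=val["BODE"],
        SGRQ=val["SGRQ"],
        sixMWT=val["sixMWT"],
        smoking_duration=smoking_duration,
        smoking_status=smoking_status,
        age=val["age"],
        sex="f" if rng.random() < 0.5 else "m",
        BMI=val["BMI"],
    )
    return study, truth, clinical


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate ``n_per_stage`` subjects per stage with round-robin site
    assignment and independent per-subject RNG substreams."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    site_stream, *subject_streams = ss.spawn(1 + config.n_per_stage * len(STAGES))
    site_effects = _site_effects(config, np.random.default_rng(site_stream))
    subjects: list[SubjectBundle] = []
    i = 0
    for stage in STAGES:
        for _ in range(config.n_per_stage):
            rng = np.random.default_rng(subject_streams[i])
            sid = f"S{i:04d}"
            study, truth, clinical = generate_subject(
                stage, config, rng, subject_id=sid, site_id=i % config.n_sites,
                site_effects=site_effects,
            )
            subjects.append(SubjectBundle(study, truth, clinical))
            i += 1
    return Cohort(config=config, subjects=subjects)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _config_to_jsonable(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict:
    """Write the cohort to ``out_dir``: per-subject NIfTI volumes (insp, exp,
    mask, truth), a clinical CSV, a ground-truth CSV, and a JSON manifest.

    Returns the manifest dict.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spacing = cohort.config.voxel_spacing_mm
    affine = np.diag(list(spacing) + [1.0])
    files: dict[str, dict[str, str]] = {}
    for s in cohort.subjects:
        sid = s.study.subject_id
        entry = {}
        for name, arr in (
            ("insp", s.study.insp.astype(np.float32)),
            ("exp", s.study.exp_registered.astype(np.float32)),
            ("mask", s.study.lung_mask.astype(np.uint8)),
            ("truth", s.truth.tissue_labelmap.astype(np.uint8)),
        ):
            path = out / f"{sid}_{name}.nii.gz"
            nib.save(nib.Nifti1Image(arr, affine), str(path))
            entry[name] = path.name
        files[sid] = entry
    clinical_path = out / "clinical.csv"
    truth_path = out / "truth.csv"
    cohort.clinical_frame().to_csv(clinical_path, index=False)
    cohort.truth_frame().to_csv(truth_path, index=False)
    manifest = {
        "seed": cohort.config.seed,
        "n_subjects": len(cohort.subjects),
        "stages": list(STAGES),
        "config": _config_to_jsonable(cohort.config),
        "files": files,
        "clinical_csv": clinical_path.name,
        "truth_csv": truth_path.name,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_cohort(in_dir: str | Path) -> Cohort:
    """Rebuild a :class:`Cohort` from a directory written by :func:`write_cohort`."""
    import nibabel as nib

    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_d = manifest["config"]
    cfg = CohortConfig(
        n_per_stage=cfg_d["n_per_stage"],
        grid_shape=tuple(cfg_d["grid_shape"]),
        voxel_spacing_mm=tuple(cfg_d["voxel_spacing_mm"]),
        stage_burden_means={k: tuple(v) for k, v in cfg_d["stage_burden_means"].items()},
        burden_concentration=cfg_d["burden_concentration"],
        hu_models={
            cls: {ph: HUModel(**m) for ph, m in phases.items()}
            for cls, phases in cfg_d["hu_models"].items()
        },
        clinical_coeffs={k: ClinicalCoeff(**v) for k, v in cfg_d["clinical_coeffs"].items()},
        n_sites=cfg_d["n_sites"],
        site_sd=cfg_d["site_sd"],
        lesion_radius_range=tuple(cfg_d["lesion_radius_range"]),
        seed=cfg_d["seed"],
    )
    clinical = pd.read_csv(src / manifest["clinical_csv"])
    clinical = clinical.set_index("subject_id", drop=False)
    subjects = []
    for sid, entry in manifest["files"].items():
        vols = {k: np.asarray(nib.load(str(src / v)).dataobj) for k, v in entry.items()}
        row = clinical.loc[sid]
        study = PairedCTStudy(
            subject_id=sid,
            insp=vols["insp"].astype(np.float32),
            exp_registered=vols["exp"].astype(np.float32),
            lung_mask=vols["mask"].astype(bool),
            stage=str(row["stage"]),
            site_id=int(row["site_id"]),
            voxel_spacing_mm=cfg.voxel_spacing_mm,
        )
        labels = vols["truth"].astype(np.uint8)
        n_lung = int(study.lung_mask.sum())
        truth = GroundTruth(
            labels,
            float((labels == TISSUE_EMPH).sum() / n_lung),
            float((labels == TISSUE_FSAD).sum() / n_lung),
        )
        clin_kwargs = {
            f.name: row[f.name] for f in dataclasses.fields(ClinicalRecord) if f.name != "subject_id"
        }
        clin = ClinicalRecord(subject_id=sid, **clin_kwargs)
        subjects.append(SubjectBundle(study, truth, clin))
    return Cohort(config=cfg, subjects=subjects)
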