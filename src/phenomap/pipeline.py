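"""End-to-end orchestration: simulate -> PRM -> features -> anomaly ->
cluster -> stats -> report, with one JSON-validated config and plain-file
stage outputs (NIfTI/CSV/JSON) so every stage can be run and inspected
standalone."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import anomaly as anomaly_mod
from . import latent as latent_mod
from . import stats as stats_mod
from .patches import LatentFeatures, plan_patches
from .prm import compute_prm
from .synthetic import STAGES, Cohort, CohortConfig, generate_cohort, load_cohort, write_cohort

log = logging.getLogger("phenomap")

CLINICAL_VARS = (
    "FEV1pp",
    "FEV1_FVC",
    "TLC",
    "FRC",
    "FRC_TLC",
    "BODE",
    "SGRQ",
    "sixMWT",
    "smoking_duration",
)
LMM_BASELINE = ("age", "sex", "BMI", "smoking_status", "smoking_duration")
LMM_OUTCOMES = ("FEV1pp", "FEV1_FVC", "FRC", "TLC", "FRC_TLC", "BODE", "SGRQ", "sixMWT")


class CohortParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_stage: int = 10
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    n_sites: int = 4
    site_sd: float = 3.0


class FeatureParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    featurizer: Literal["histogram", "contrastive"] = "histogram"
    feature_dim: int = 512
    patch_size: int = 50
    overlap_fraction: float = 0.2
    min_lung_fraction: float = 0.2


class AnomalyParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    family: Literal["gaussian", "gaussian_mixture"] = "gaussian_mixture"
    k_min: int = 1
    k_max: int = 8
    whiten_dim: int = 32
    aggregation: Literal["mean", "median", "max"] = "mean"
    percentiles: tuple[float, float] = (5.0, 95.0)


class ClusterParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    methods: tuple[str, ...] = ("minibatch_kmeans", "gaussian_mixture")
    k_min: int = 2
    k_max: int = 8
    pa_reps: int = 100
    pa_percentile: float = 95.0
    tsne_perplexity: float = 30.0


class StatsParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_boot: int = 10_000
    alpha: float = 0.05
    holm: bool = True


class AnalysisConfig(BaseModel):
    """Full pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    out_dir: str
    cohort_dir: str | None = None
    run_simulate: bool = True
    cohort: CohortParams = Field(default_factory=CohortParams)
    features: FeatureParams = Field(default_factory=FeatureParams)
    anomaly: AnomalyParams = Field(default_factory=AnomalyParams)
    cluster: ClusterParams = Field(default_factory=ClusterParams)
    stats: StatsParams = Field(default_factory=StatsParams)
    seed: int = 0


def config_schema() -> dict:
    return AnalysisConfig.model_json_schema()


def _stage_seed(master: int, stage: str) -> int:
    import zlib

    h = np.random.SeedSequence((master, zlib.crc32(stage.encode()))).generate_state(1)[0]
    return int(h % (2**31))


def _write_nifti(arr: np.ndarray, spacing: Sequence[float], path: Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(arr), np.diag(list(spacing) + [1.0])), str(path))


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every stage and return the results manifest (also written to
    ``out_dir/manifest.json``).  Deterministic given the config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.model_dump(), "stages": {}}

    # -- simulate -----------------------------------------------------------
    cohort_dir = Path(config.cohort_dir) if config.cohort_dir else out / "cohort"
    if config.run_simulate:
        log.info("simulate: %d subjects/stage, seed %d", config.cohort.n_per_stage, config.seed)
        ccfg = CohortConfig(
            n_per_stage=config.cohort.n_per_stage,
            grid_shape=tuple(config.cohort.grid_shape),
            n_sites=config.cohort.n_sites,
            site_sd=config.cohort.site_sd,
            seed=_stage_seed(config.seed, "simulate"),
        )
        cohort = generate_cohort(ccfg)
        write_cohort(cohort, cohort_dir)
    else:
        if not (cohort_dir / "manifest.json").exists():
            raise FileNotFoundError(
                f"no cohort at {cohort_dir}; run the simulate stage or point cohort_dir at one"
            )
        cohort = load_cohort(cohort_dir)
    manifest["stages"]["simulate"] = {"cohort_dir": str(cohort_dir), "n_subjects": len(cohort.subjects)}

    # -- prm ---------------------------------------------------------------
    prm_dir = out / "prm"
    prm_dir.mkdir(exist_ok=True)
    exemplars = {}
    for s in cohort.subjects:
        if s.study.stage not in exemplars:
            exemplars[s.study.stage] = s.study.subject_id
    prm_rows = []
    prm_by_sid = {}
    for s in cohort.subjects:
        res = compute_prm(s.study)
        prm_by_sid[s.study.subject_id] = res
        prm_rows.append(
            {
                "subject_id": s.study.subject_id,
                "stage": s.study.stage,
                "site_id": s.study.site_id,
                "pct_normal": res.pct_normal,
                "pct_fsad": res.pct_fsad,
                "pct_emph": res.pct_emph,
                "pct_excluded": res.pct_excluded,
                "laa950_pct": res.laa950_pct,
                "laa856_pct": res.laa856_pct,
            }
        )
        if exemplars[s.study.stage] == s.study.subject_id:
            _write_nifti(
                res.labelmap.astype(np.uint8),
                s.study.voxel_spacing_mm,
                prm_dir / f"{s.study.subject_id}_prm.nii.gz",
            )
    prm_df = pd.DataFrame(prm_rows)
    prm_df.to_csv(prm_dir / "prm.csv", index=False)
    with open(prm_dir / "prm_codes.json", "w") as fh:
        json.dump({"0": "background", "1": "Normal", "2": "fSAD", "3": "Emph", "4": "Excluded"}, fh)
    manifest["stages"]["prm"] = {"table": str(prm_dir / "prm.csv")}

    # -- features ----------------------------------------------------------
    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    fp = config.features
    if fp.featurizer == "contrastive":
        from .contrastive import ContrastiveEncoder
        from .patches import embed_cohort, extract_patch_pairs

        enc = ContrastiveEncoder(dim=min(fp.feature_dim, 64), seed=_stage_seed(config.seed, "features"))
        grid0 = plan_patches(
            cohort.subjects[0].study.lung_mask, fp.patch_size, fp.overlap_fraction, fp.min_lung_fraction
        )
        train_patches = [
            p
            for s in cohort.subjects[:: max(1, len(cohort.subjects) // 20)]
            for p in extract_patch_pairs(s.study, grid0)
        ]
        enc.train(train_patches, epochs=5, seed=_stage_seed(config.seed, "features"))
        features = embed_cohort(
            cohort,
            featurizer=enc.featurizer(),
            featurizer_id="contrastive",
            patch_size=fp.patch_size,
            overlap_fraction=fp.overlap_fraction,
            min_lung_fraction=fp.min_lung_fraction,
        )
    else:
        from .patches import embed_cohort

        features = embed_cohort(
            cohort,
            patch_size=fp.patch_size,
            overlap_fraction=fp.overlap_fraction,
            min_lung_fraction=fp.min_lung_fraction,
            feature_dim=fp.feature_dim,
        )
    np.savetxt(feat_dir / "features.csv", features.matrix, delimiter=",", fmt="%.8g")
    features.meta.to_csv(feat_dir / "meta.csv", index=False)
    manifest["stages"]["features"] = {
        "featurizer": features.featurizer_id,
        "n_patches": int(features.matrix.shape[0]),
        "dim": int(features.matrix.shape[1]),
    }

    # -- anomaly -----------------------------------------------------------
    anom_dir = out / "anomaly"
    anom_dir.mkdir(exist_ok=True)
    ap = config.anomaly
    ref_sel = anomaly_mod.select_reference_patches(features)
    density = anomaly_mod.fit_reference_density(
        features.matrix[ref_sel],
        family=ap.family,
        k_range=range(ap.k_min, ap.k_max + 1),
        seed=_stage_seed(config.seed, "anomaly"),
        whiten_dim=ap.whiten_dim,
    )
    patient_df, patch_scores, bounds = anomaly_mod.score_cohort(
        features, density, ap.aggregation, tuple(ap.percentiles)
    )
    scores_df = features.meta[["subject_id", "origin_x", "origin_y", "origin_z"]].copy()
    scores_df["score"] = patch_scores
    scores_df.to_csv(anom_dir / "patch_scores.csv", index=False)
    patient_df.to_csv(anom_dir / "patient_scores.csv", index=False)
    with open(anom_dir / "density.json", "w") as fh:
        json.dump(
            {
                "family": density.family,
                "n_components": density.n_components,
                "n_train": density.n_train,
                "bic_table": {str(k): v for k, v in density.bic_table.items()},
                "bounds_p5_p95": list(bounds),
                "weights": density.weights.tolist(),
                "means": density.means.tolist(),
                "covariances": density.covariances.tolist(),
            },
            fh,
        )
    grid = plan_patches(
        cohort.subjects[0].study.lung_mask, fp.patch_size, fp.overlap_fraction, fp.min_lung_fraction
    )
    meta_sid = features.meta["subject_id"].to_numpy()
    for stage, sid in exemplars.items():
        s = next(x for x in cohort.subjects if x.study.subject_id == sid)
        amap = anomaly_mod.render_anomaly_map(
            patch_scores[meta_sid == sid], grid, s.study.lung_mask, bounds
        )
        _write_nifti(amap.astype(np.float32), s.study.voxel_spacing_mm, anom_dir / f"{sid}_anomaly.nii.gz")
    manifest["stages"]["anomaly"] = {
        "family": density.family,
        "n_components": density.n_components,
        "n_reference_patches": int(ref_sel.sum()),
        "bounds": list(bounds),
    }

    # -- cluster -----------------------------------------------------------
    clus_dir = out / "cluster"
    clus_dir.mkdir(exist_ok=True)
    cp = config.cluster
    pca = latent_mod.fit_pca_with_retention(
        features.matrix, n_pa_reps=cp.pa_reps, pa_percentile=cp.pa_percentile,
        seed=_stage_seed(config.seed, "pca"),
    )
    scores = pca.transform(features.matrix)
    cmodel = latent_mod.cluster_latent(
        scores,
        methods=tuple(cp.methods),
        k_range=range(cp.k_min, cp.k_max + 1),
        seed=_stage_seed(config.seed, "cluster"),
    )
    assign_df = features.meta[["subject_id", "stage"]].copy()
    assign_df["cluster"] = cmodel.assignments
    assign_df.to_csv(clus_dir / "assignments.csv", index=False)
    cmodel.selection.to_csv(clus_dir / "selection.csv", index=False)
    volumes = latent_mod.cluster_subject_volumes(cmodel.assignments, features.meta, cmodel.k)
    volumes.to_csv(clus_dir / "subject_volumes.csv", index=False)
    with open(clus_dir / "pca.json", "w") as fh:
        json.dump(
            {
                "horn_k": pca.horn_k,
                "kaiser_k": pca.kaiser_k,
                "n_retained": pca.n_retained,
                "eigenvalues": pca.eigenvalues[:50].tolist(),
            },
            fh,
        )
    for stage, sid in exemplars.items():
        s = next(x for x in cohort.subjects if x.study.subject_id == sid)
        cmap = latent_mod.render_cluster_map(
            cmodel.assignments[meta_sid == sid], grid, s.study.lung_mask
        )
        _write_nifti(cmap.astype(np.uint8), s.study.voxel_spacing_mm, clus_dir / f"{sid}_clusters.nii.gz")
    # t-SNE: fit on the evaluation half (even subject index), transform rest
    sids = sorted(features.meta["subject_id"].unique())
    eval_sids = set(sids[::2])
    is_eval = features.meta["subject_id"].isin(eval_sids).to_numpy()
    if is_eval.sum() >= 50:
        emb_fit, emb_t = latent_mod.tsne_embed(
            features.matrix[is_eval],
            features.matrix[~is_eval] if (~is_eval).any() else None,
            seed=_stage_seed(config.seed, "tsne"),
            perplexity=cp.tsne_perplexity,
        )
        emb = np.zeros((len(features.meta), 2))
        emb[is_eval] = emb_fit
        if emb_t is not None:
            emb[~is_eval] = emb_t
        emb_df = features.meta[["subject_id", "stage", "patch_emph_pct", "patch_airtrap_pct"]].copy()
        emb_df["set"] = np.where(is_eval, "evaluation", "test")
        emb_df["tsne_1"], emb_df["tsne_2"] = emb[:, 0], emb[:, 1]
        emb_df.to_csv(clus_dir / "embeddings.csv", index=False)
    manifest["stages"]["cluster"] = {
        "horn_k": pca.horn_k,
        "kaiser_k": pca.kaiser_k,
        "method": cmodel.method,
        "k": cmodel.k,
    }

    # -- stats -------------------------------------------------------------
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    sp = config.stats
    merged = (
        cohort.clinical_frame()
        .merge(prm_df.drop(columns=["stage", "site_id"]), on="subject_id")
        .merge(patient_df[["subject_id", "patient_score"]], on="subject_id")
        .merge(volumes.drop(columns=["stage"]), on="subject_id")
    )
    merged["stage_order"] = merged["stage"].map({s: i for i, s in enumerate(STAGES)})
    merged = merged.sort_values("subject_id").reset_index(drop=True)
    merged.to_csv(stats_dir / "merged.csv", index=False)
    cluster_cols = [c for c in volumes.columns if c.startswith("cluster_")]
    measures = ["pct_emph", "pct_fsad", "pct_normal", "patient_score"] + cluster_cols

    trend_rows = []
    for m in measures:
        groups = [merged.loc[merged["stage"] == s, m].to_numpy() for s in STAGES]
        try:
            res = stats_mod.jonckheere_terpstra(groups, alternative="two-sided")
            trend_rows.append(
                {"measure": m, "jt": res.jt_statistic, "z": res.z, "p": res.p}
            )
        except ValueError:
            trend_rows.append({"measure": m, "jt": np.nan, "z": np.nan, "p": np.nan})
    trend_df = pd.DataFrame(trend_rows)
    trend_df.to_csv(stats_dir / "trend.csv", index=False)

    tukey = stats_mod.tukey_posthoc(
        merged["patient_score"].to_numpy(), merged["stage"].to_numpy()
    )
    tukey.to_csv(stats_dir / "tukey_anomaly.csv", index=False)

    seed_corr = _stage_seed(config.seed, "bootstrap")
    corr_rows = []
    for m in measures:
        for v in CLINICAL_VARS:
            try:
                c = stats_mod.pearson_bootstrap_ci(
                    merged[m].to_numpy(), merged[v].to_numpy(), n_boot=sp.n_boot,
                    seed=seed_corr, alpha=sp.alpha,
                )
            except ValueError:
                continue
            corr_rows.append(
                {
                    "measure": m,
                    "clinical": v,
                    "r": c.r,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "p": c.p,
                    "band": c.band_label,
                    "n": c.n,
                }
            )
    corr_df = pd.DataFrame(corr_rows)
    if sp.holm and len(corr_df):
        corr_df["p_holm"] = stats_mod.holm_adjust(corr_df["p"].to_numpy())
    corr_df.to_csv(stats_dir / "correlations.csv", index=False)

    diff_rows = []
    for prm_m in ("pct_emph", "pct_fsad"):
        for v in CLINICAL_VARS:
            try:
                d = stats_mod.zou_correlation_difference(
                    merged[v].to_numpy(), merged["patient_score"].to_numpy(), merged[prm_m].to_numpy()
                )
            except ValueError:
                continue
            diff_rows.append(
                {
                    "clinical": v,
                    "vs": prm_m,
                    "r_anomaly": d.r_jk,
                    "r_prm": d.r_jh,
                    "diff": d.diff,
                    "ci_low": d.ci_low,
                    "ci_high": d.ci_high,
                    "significant": d.significant,
                }
            )
    pd.DataFrame(diff_rows).to_csv(stats_dir / "corr_differences.csv", index=False)

    lmm_rows = []
    for outcome in LMM_OUTCOMES:
        baseline = [p for p in LMM_BASELINE if p != outcome]
        for prm_m in ("pct_fsad", "pct_emph"):
            try:
                base, with_prm, p_prm = stats_mod.fit_lmm_and_lrt(
                    merged, outcome, baseline, [prm_m]
                )
                _, with_anom, p_anom = stats_mod.fit_lmm_and_lrt(
                    merged, outcome, baseline + [prm_m], ["patient_score"]
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            lmm_rows.append(
                {
                    "outcome": outcome,
                    "prm_measure": prm_m,
                    "r2_baseline": base.r2_conditional_adjusted,
                    "r2_prm": with_prm.r2_conditional_adjusted,
                    "r2_prm_anomaly": with_anom.r2_conditional_adjusted,
                    "lrt_p_prm": p_prm,
                    "lrt_p_anomaly": p_anom,
                }
            )
    pd.DataFrame(lmm_rows).to_csv(stats_dir / "lmm.csv", index=False)

    ba_rows = []
    for c in cluster_cols:
        prm_vals = np.concatenate([merged["pct_emph"].to_numpy(), merged["pct_fsad"].to_numpy()])
        clus_vals = np.concatenate([merged[c].to_numpy() * 100.0] * 2)
        try:
            fit = stats_mod.bland_altman_regression_loa(prm_vals, clus_vals, scale="log")
        except ValueError:
            continue
        ba_rows.append(
            {
                "cluster": c,
                "bias_intercept": fit.bias_intercept,
                "bias_slope": fit.bias_slope,
                "loa_halfwidth": fit.loa_halfwidth,
                "n": fit.n,
                "n_excluded": fit.n_excluded,
            }
        )
    pd.DataFrame(ba_rows).to_csv(stats_dir / "bland_altman.csv", index=False)

    # Fig-6 analog: patient-level anomaly vs PRM correlations
    r_emph = stats_mod.pearson_bootstrap_ci(
        merged["patient_score"].to_numpy(), merged["pct_emph"].to_numpy(),
        n_boot=sp.n_boot, seed=seed_corr,
    )
    r_fsad = stats_mod.pearson_bootstrap_ci(
        merged["patient_score"].to_numpy(), merged["pct_fsad"].to_numpy(),
        n_boot=sp.n_boot, seed=seed_corr,
    )
    with open(stats_dir / "anomaly_vs_prm.json", "w") as fh:
        json.dump(
            {
                "r_anomaly_vs_emph": r_emph.r,
                "r_anomaly_vs_fsad": r_fsad.r,
                "p_anomaly_vs_emph": r_emph.p,
                "p_anomaly_vs_fsad": r_fsad.p,
            },
            fh,
        )
    manifest["stages"]["stats"] = {"dir": str(stats_dir)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.3g}") -> str:
    if df.empty:
        return "(none)"

    def fmt(v):
        return floatfmt.format(v) if isinstance(v, float) else str(v)

    head = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = "\n".join("| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False))
    return "\n".join([head, sep, body])


def make_report(results_dir: str | Path) -> Path:
    """Render the Markdown report (per-stage trends, correlation table with
    CIs/bands, mixed-model comparison, agreement analysis, overlay mosaics)
    from a completed pipeline output directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import nibabel as nib

    out = Path(results_dir)
    stats_dir = out / "stats"
    required = ["merged.csv", "trend.csv", "correlations.csv", "lmm.csv", "bland_altman.csv"]
    missing = [f for f in required if not (stats_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"stats outputs missing: {missing}; run the stats stage first")
    rep_dir = out / "report"
    rep_dir.mkdir(exist_ok=True)
    def _read(name: str) -> pd.DataFrame:
        try:
            return pd.read_csv(stats_dir / name)
        except pd.errors.EmptyDataError:
            return pd.DataFrame()

    merged = _read("merged.csv")
    trend = _read("trend.csv")
    corr = _read("correlations.csv")
    lmm = _read("lmm.csv")
    ba = _read("bland_altman.csv")
    cluster_cols = [c for c in merged.columns if c.startswith("cluster_")]
    stages_present = [s for s in STAGES if s in set(merged["stage"])]

    # stage distribution boxplots
    panels = ["pct_emph", "pct_fsad", "patient_score"] + cluster_cols
    fig, axes = plt.subplots(1, len(panels), figsize=(3.2 * len(panels), 3.4))
    for ax, m in zip(np.atleast_1d(axes), panels):
        ax.boxplot(
            [merged.loc[merged["stage"] == s, m] for s in stages_present],
            tick_labels=stages_present,
        )
        ax.set_title(m)
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(rep_dir / "stage_distributions.png", dpi=110)
    plt.close(fig)

    # anomaly vs PRM scatter
    with open(stats_dir / "anomaly_vs_prm.json") as fh:
        avp = json.load(fh)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, m, key in zip(
        axes, ["pct_emph", "pct_fsad"], ["r_anomaly_vs_emph", "r_anomaly_vs_fsad"]
    ):
        x, y = merged["patient_score"], merged[m]
        ax.scatter(x, y, s=12, alpha=0.7)
        b, a = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 20)
        ax.plot(xs, a + b * xs, "r-")
        ax.set_xlabel("patient anomaly score")
        ax.set_ylabel(m)
        ax.set_title(f"r = {avp[key]:.2f}")
    fig.tight_layout()
    fig.savefig(rep_dir / "anomaly_vs_prm.png", dpi=110)
    plt.close(fig)

    # Bland-Altman panels
    if len(ba):
        fig, axes = plt.subplots(1, len(ba), figsize=(4.2 * len(ba), 3.6), squeeze=False)
        for ax, (_, row) in zip(axes[0], ba.iterrows()):
            c = row["cluster"]
            prm_vals = np.concatenate([merged["pct_emph"], merged["pct_fsad"]])
            cl_vals = np.concatenate([merged[c] * 100.0] * 2)
            ok = (prm_vals > 0) & (cl_vals > 0)
            D = np.log(prm_vals[ok]) - np.log(cl_vals[ok])
            A = (np.log(prm_vals[ok]) + np.log(cl_vals[ok])) / 2
            ax.scatter(A, D, s=10, alpha=0.7)
            xs = np.linspace(A.min(), A.max(), 20)
            bias = row["bias_intercept"] + row["bias_slope"] * xs
            ax.plot(xs, bias, "k:")
            ax.plot(xs, bias + row["loa_halfwidth"], "k--")
            ax.plot(xs, bias - row["loa_halfwidth"], "k--")
            ax.set_title(f"PRM vs {c}")
            ax.set_xlabel("A (log mean)")
            ax.set_ylabel("D (log diff)")
        fig.tight_layout()
        fig.savefig(rep_dir / "bland_altman.png", dpi=110)
        plt.close(fig)

    # coronal overlay mosaic for exemplar subjects
    cohort_dir = Path(json.load(open(out / "manifest.json"))["stages"]["simulate"]["cohort_dir"])
    cmanifest = json.load(open(cohort_dir / "manifest.json"))
    clin = pd.read_csv(cohort_dir / cmanifest["clinical_csv"])
    exemplar_sids = [clin.loc[clin["stage"] == s, "subject_id"].iloc[0] for s in stages_present]
    rows = []
    for sid in exemplar_sids:
        prm_map = out / "prm" / f"{sid}_prm.nii.gz"
        anom_map = out / "anomaly" / f"{sid}_anomaly.nii.gz"
        clus_map = out / "cluster" / f"{sid}_clusters.nii.gz"
        if prm_map.exists() and anom_map.exists() and clus_map.exists():
            rows.append((sid, prm_map, anom_map, clus_map))
    if rows:
        fig, axes = plt.subplots(len(rows), 4, figsize=(12, 2.6 * len(rows)), squeeze=False)
        for i, (sid, prm_p, an_p, cl_p) in enumerate(rows):
            insp = np.asarray(nib.load(str(cohort_dir / cmanifest["files"][sid]["insp"])).dataobj)
            ymid = insp.shape[1] // 2
            vols = [
                (insp[:, ymid, :].T, "gray", "insp CT"),
                (np.asarray(nib.load(str(prm_p)).dataobj)[:, ymid, :].T, "viridis", "PRM"),
                (np.asarray(nib.load(str(an_p)).dataobj)[:, ymid, :].T, "hot", "anomaly"),
                (np.asarray(nib.load(str(cl_p)).dataobj)[:, ymid, :].T, "tab10", "clusters"),
            ]
            for j, (img, cmap, title) in enumerate(vols):
                axes[i][j].imshow(img, cmap=cmap, origin="lower")
                axes[i][j].set_axis_off()
                if i == 0:
                    axes[i][j].set_title(title)
                if j == 0:
                    axes[i][j].set_ylabel(sid)
        fig.tight_layout()
        fig.savefig(rep_dir / "overlay_mosaic.png", dpi=110)
        plt.close(fig)

    clinical_in_cohort = [v for v in CLINICAL_VARS if v in merged.columns]
    md = [
        "# Phenotyping comparison report",
        "",
        f"Subjects: {merged['subject_id'].nunique()}  |  stages: {', '.join(stages_present)}",
        f"Clinical variables: {', '.join(clinical_in_cohort)}",
        "",
        "## Ordered trend over disease stages (Jonckheere-Terpstra)",
        _md_table(trend),
        "",
        "## Correlations with clinical variables (bootstrap CIs, Holm-adjusted p)",
        _md_table(corr),
        "",
        "## Mixed-model comparison (adjusted conditional R^2, LRT)",
        _md_table(lmm),
        "",
        "## Agreement of PRM and cluster volumes (regression-based LoA, log scale)",
        _md_table(ba),
        "",
        "![stage distributions](report/stage_distributions.png)",
        "![anomaly vs PRM](report/anomaly_vs_prm.png)",
        "![Bland-Altman](report/bland_altman.png)",
        "![overlays](report/overlay_mosaic.png)",
        "",
    ]
    report_path = rep_dir / "report.md"
    report_path.write_text("\n".join(md))
    return report_path
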