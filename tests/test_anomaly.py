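"""Reference-density anomaly scoring: patch selection rules, density
estimation, NLL oracle checks, aggregation, map rendering."""

import numpy as np
import pandas as pd
import pytest

from phenomap import (
    aggregate_patient_score,
    fit_reference_density,
    render_anomaly_map,
    score_patches,
    select_reference_patches,
)
from phenomap.anomaly import EmptyReferenceError
from phenomap.patches import LatentFeatures, plan_patches


def _features(stages, emph_pcts):
    n = len(stages)
    meta = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "stage": stages,
            "site_id": 0,
            "origin_x": 0,
            "origin_y": 0,
            "origin_z": 0,
            "lung_fraction": 1.0,
            "patch_emph_pct": emph_pcts,
            "patch_airtrap_pct": 0.0,
        }
    )
    return LatentFeatures(np.zeros((n, 3)), meta, "test")


@pytest.mark.parametrize(
    "stage,emph_pct,included",
    [
        ("GOLD0", 0.0, True),
        ("GOLD0", 2.0, False),
        ("GOLD3", 0.0, False),
        ("control", 0.5, True),
    ],
)
def test_reference_selection_rules(stage, emph_pct, included):
    feats = _features([stage, "control"], [emph_pct, 0.0])
    sel = select_reference_patches(feats)
    assert bool(sel[0]) is included


def test_empty_reference_raises():
    feats = _features(["GOLD4"], [50.0])
    with pytest.raises(EmptyReferenceError):
        select_reference_patches(feats)


def test_gaussian_estimator_consistency():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((5000, 5))
    den = fit_reference_density(X, family="gaussian", whiten_dim=None)
    assert np.abs(den.means[0]).max() < 0.05
    assert np.abs(np.diag(den.covariances[0]) - 1).max() < 0.1


def test_bic_selects_two_components_for_two_blobs():
    rng = np.random.default_rng(1)
    X = np.vstack(
        [rng.standard_normal((400, 5)) - 4.0, rng.standard_normal((400, 5)) + 4.0]
    )
    den = fit_reference_density(X, family="gaussian_mixture", k_range=range(1, 5),
                                seed=2, whiten_dim=None)
    assert den.n_components == 2


def test_gaussian_nll_closed_form_at_mean():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((500, 4)) @ np.diag([1.0, 2.0, 0.5, 1.5])
    den = fit_reference_density(X, family="gaussian", whiten_dim=None, reg_covar=0.0)
    d = 4
    expected = 0.5 * np.log((2 * np.pi) ** d * np.linalg.det(den.covariances[0]))
    got = den.nll(den.means)[0]
    assert got == pytest.approx(expected, abs=1e-8)


def test_scores_monotone_in_mahalanobis_and_match_logpdf_oracle():
    from scipy.stats import multivariate_normal

    rng = np.random.default_rng(3)
    X = rng.standard_normal((2000, 3))
    den = fit_reference_density(X, family="gaussian", whiten_dim=None)
    pts = np.array([[0.1, 0, 0], [1, 1, 0], [3, 2, 1], [5, 5, 5]])
    scores = score_patches(den, pts)
    mean, cov = den.means[0], den.covariances[0]
    inv = np.linalg.inv(cov)
    maha = np.array([float((p - mean) @ inv @ (p - mean)) for p in pts])
    assert np.all(np.diff(scores[np.argsort(maha)]) > 0)
    oracle = -multivariate_normal.logpdf(pts, mean=mean, cov=cov)
    assert np.allclose(scores, oracle, atol=1e-8)


def test_whitened_scores_respect_transform():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((300, 40))
    den = fit_reference_density(X, family="gaussian", whiten_dim=8, seed=0)
    assert den.means.shape[1] <= 8
    s = score_patches(den, X)
    assert np.isfinite(s).all()


def test_aggregation_rules():
    assert aggregate_patient_score(np.array([3.5])) == 3.5
    assert aggregate_patient_score(np.full(7, 2.0)) == 2.0
    x = np.array([1.0, 2.0, 6.0])
    assert aggregate_patient_score(x, "mean") == pytest.approx(x.mean())
    assert aggregate_patient_score(x, "median") == 2.0
    assert aggregate_patient_score(x, "max") == 6.0
    with pytest.raises(ValueError):
        aggregate_patient_score(np.array([]))


def test_anomaly_map_normalization_and_averaging():
    mask = np.ones((100, 50, 50), bool)
    grid = plan_patches(mask, patch_size=50, overlap_fraction=0.2, min_lung_fraction=0.0)
    # origins on x: 0, 40, 50 -> voxel x=45 lies in patches 0 and 1
    scores = np.array([10.0, 20.0, 80.0])
    p5, p95 = 10.0, 80.0
    vol = render_anomaly_map(scores, grid, mask, (p5, p95))
    assert vol[0, 0, 0] == 0.0  # at p5
    assert vol[95, 0, 0] == 1.0  # at p95
    raw_overlap = (10.0 + 20.0) / 2
    assert vol[45, 0, 0] == pytest.approx((raw_overlap - p5) / (p95 - p5))
    assert vol.min() >= 0.0 and vol.max() <= 1.0


def test_anomaly_map_degenerate_bounds_warns_zero():
    mask = np.ones((50, 50, 50), bool)
    grid = plan_patches(mask)
    with pytest.warns(UserWarning):
        vol = render_anomaly_map(np.array([5.0]), grid, mask, (5.0, 5.0))
    assert (vol == 0).all()


def test_reference_patches_score_below_lesion_patches(features20):
    """Held-out normal-like patches score lower than lesion-rich patches."""
    sel = select_reference_patches(features20)
    idx = np.flatnonzero(sel)
    train, held = idx[::2], idx[1::2]
    den = fit_reference_density(features20.matrix[train], seed=5)
    lesion = (features20.meta["patch_emph_pct"] > 20).to_numpy()
    s_ref = score_patches(den, features20.matrix[held])
    s_les = score_patches(den, features20.matrix[lesion])
    assert np.median(s_ref) < np.median(s_les)
    assert s_ref.mean() < s_les.mean()
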