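"""Shared fixtures: session-scoped synthetic cohorts and pipeline runs so
expensive generation happens once."""

from __future__ import annotations

import numpy as np
import pytest

from phenomap import CohortConfig, embed_cohort, generate_cohort
from phenomap.pipeline import AnalysisConfig, run_pipeline


def small_config(**kw) -> CohortConfig:
    """Small-grid config for fast unit tests (patches clamp to the grid)."""
    kw.setdefault("grid_shape", (36, 36, 28))
    kw.setdefault("n_per_stage", 2)
    return CohortConfig(**kw)


@pytest.fixture(scope="session")
def cohort30():
    """30-per-stage cohort at the default calibration, for recovery and
    calibration checks."""
    return generate_cohort(CohortConfig(n_per_stage=30, seed=20240301))


@pytest.fixture(scope="session")
def cohort20():
    """20-per-stage cohort for the anomaly-pipeline trend checks."""
    return generate_cohort(CohortConfig(n_per_stage=20, seed=20240302))


@pytest.fixture(scope="session")
def features20(cohort20):
    return embed_cohort(cohort20)


def demo_config(out_dir: str, seed: int = 7) -> AnalysisConfig:
    """The default demo pipeline configuration: 10 subjects per stage on
    64^3 grids."""
    return AnalysisConfig(
        out_dir=out_dir,
        cohort=dict(n_per_stage=10, grid_shape=(64, 64, 64)),
        seed=seed,
    )


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("demo")
    manifest = run_pipeline(demo_config(str(out)))
    return out, manifest
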