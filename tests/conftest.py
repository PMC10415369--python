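"""Shared fixtures: small synthetic cohorts and one full pipeline run.

The ``paper_like_run`` fixture executes the complete repeated-split analysis
once per session (cohort with the step-wise effect gradient, 150 iterations)
and is shared by the specificity, weight-map and association tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from gmdclassify import (
    MaskConfig,
    PipelineConfig,
    build_gm_mask,
    cohort_spec,
    extract_features,
    generate_cohort,
    run_scheme,
)

SMALL_GROUPS = {"B1": 30, "B2": 30, "B3": 30, "CON": 30}


def make_cohort(preset="paper_like", grid=12, seed=0, group_sizes=None, **overrides):
    spec = cohort_spec(
        preset=preset, grid_dims=(grid,) * 3, seed=seed, group_sizes=group_sizes, **overrides
    )
    return generate_cohort(spec)


def cohort_features(cohort):
    mask = build_gm_mask(
        cohort.gm_prob, cohort.wm_prob, MaskConfig(), affine=cohort.affine
    )
    return mask, extract_features(cohort.images, mask, subject_ids=cohort.subject_ids)


@pytest.fixture(scope="session")
def paper_like_run():
    """Full biotype-scheme run on the calibrated step-wise-gradient cohort."""
    cohort = make_cohort(preset="paper_like", grid=24, seed=1)
    mask, features = cohort_features(cohort)
    config = PipelineConfig(n_iterations=150, master_seed=101, collect_weights=True)
    report, records, weights = run_scheme(features, cohort.subjects, "biotype", config)
    return {
        "cohort": cohort,
        "mask": mask,
        "features": features,
        "config": config,
        "report": report,
        "records": records,
        "weights": weights,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
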