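import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from interomap.cohort import (
    GroundTruth,
    RoiSpec,
    SimConfig,
    build_grid_rois,
    default_ground_truth,
    simulate_cohort,
)
from interomap.conditioning import condition_subject

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid_rois():
    """Default 21-seed ROI layout on a small 16^3 grid."""
    return build_grid_rois((16, 16, 16), rng_seed=1)


@pytest.fixture(scope="session")
def two_seed_layout():
    """Two cortical spheres only, for closed-form coupling checks."""
    return build_grid_rois(
        (12, 12, 12), RoiSpec(cortical=("A", "B"), subcortical_sizes=()), rng_seed=0
    )


@pytest.fixture(scope="session")
def tiny_cohort(grid_rois):
    """Small conditioned cohort with the default planted structure."""
    grid, rois = grid_rois
    cfg = SimConfig(n_subjects=8, n_runs=2, frames_per_run=80)
    cohort, confounds = simulate_cohort(grid, rois, default_ground_truth(), cfg, rng_seed=7)
    conditioned = []
    for ts, conf in zip(cohort, confounds):
        out, _ = condition_subject(ts, conf)
        conditioned.append(out)
    return grid, rois, conditioned, confounds


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
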