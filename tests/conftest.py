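"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from npabench import CohortConfig, RBParams, generate_cohort
from npabench.synthetic import healthy_cohort_config


def noiseless(cfg: CohortConfig) -> CohortConfig:
    cfg.noise_model = {"a": 0.0, "b": 0.0}
    cfg.shadow_model = dict(cfg.shadow_model, prob=0.0)
    return cfg


@pytest.fixture(scope="session")
def healthy_noiseless_cohort():
    """Six clean healthy eyes (all slabs) for calibration-style tests."""
    cfg = noiseless(healthy_cohort_config(6, seed=2, id_prefix="HN"))
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def dr_noiseless_cohort():
    """Eight clean referable-severity eyes with planted lesions."""
    cfg = noiseless(
        CohortConfig(
            n_participants=8, eyes_per_participant=1, visits_per_eye=1, seed=31,
            id_prefix="DN",
        )
    )
    cfg.severity_weights = {43: 1.0}
    cfg.lesion_model = {
        "referable": {"mean_area_mm2": 1.2, "mean_count": 3.0, "min_lesion_mm2": 0.3}
    }
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_rb_params() -> RBParams:
    return RBParams()
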