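"""Shared fixtures: one default synthetic study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from brainmodes.modes import age_weight, finalize_modes, sweep_dimensionality
from brainmodes.preprocess import preprocess_idps
from brainmodes.simulate import SimulationConfig, generate_idp_dataset


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (1000 x 200, 5 planted modes), preprocessed."""
    cfg = SimulationConfig(rng_seed=1)
    matrix, confounds, age, truth = generate_idp_dataset(cfg)
    dense, clean, dropped = preprocess_idps(matrix, confounds, rng_seed=1)
    keep = [matrix.subject_ids.index(s) for s in clean.subject_ids]
    return {
        "config": cfg,
        "matrix": matrix,
        "confounds": confounds,
        "age": age[keep],
        "truth": truth,
        "dense": dense,
        "clean": clean,
        "dropped": dropped,
    }


@pytest.fixture(scope="session")
def discovered(study):
    """Mode discovery run on the default study (sweep + finalise)."""
    weighted, weights = age_weight(study["dense"], study["age"])
    report = sweep_dimensionality(weighted, range(4, 11), n_splits=10, rng_seed=1)
    modes = finalize_modes(
        weighted, study["dense"], report.chosen_dim, study["age"], n_runs=30, rng_seed=1
    )
    return {"weighted": weighted, "col_weights": weights, "report": report, "modes": modes}
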