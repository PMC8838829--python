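"""Session fixtures: simulated passes and the evaluation cohort.

The 45-pass cohort is simulated once per session and shared by the feature,
statistics and acceptance tests; per-pass trigger accuracy is collected in
the same sweep so the frames never have to be held in memory twice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from filletbend.feature_extraction import features_from_pass
from filletbend.frame_io import FEATURE_COLUMNS
from filletbend.motion_sensor import TriggerConfig, delimit_window
from filletbend.scene_sim import SceneGeometry, iter_cohort, make_fillet_profile, simulate_pass

COHORT_N_PER_CLASS = 15
COHORT_SEED = 42


@pytest.fixture(scope="session")
def geom() -> SceneGeometry:
    return SceneGeometry()


@pytest.fixture(scope="session")
def normal_pass(geom):
    profile = make_fillet_profile("normal", rng_seed=7)
    return simulate_pass(profile, geom, rng_seed=11, label="normal")


@pytest.fixture(scope="session")
def severe_pass(geom):
    profile = make_fillet_profile("severe", rng_seed=7)
    return simulate_pass(profile, geom, rng_seed=11, label="severe")


@pytest.fixture(scope="session")
def noisefree_passes(geom):
    """One noise-free pass per class, for exact-ground-truth comparisons."""
    passes = []
    for k, label in enumerate(("normal", "moderate", "severe")):
        profile = make_fillet_profile(label, rng_seed=100 + k)
        passes.append(simulate_pass(profile, geom, rng_seed=200 + k, label=label, noise_sigma=0.0))
    return passes


@pytest.fixture(scope="session")
def cohort_run(geom):
    """Simulate the 45-pass cohort once; collect features and trigger errors.

    Returns a dict with:
      features        - 45-row feature table (columns FEATURE_COLUMNS)
      arrival_errors  - per-pass |detected - true| arrival frame offsets
    """
    cfg = TriggerConfig.from_geometry(geom)
    rows = []
    arrival_errors = []
    for sim_pass in iter_cohort(COHORT_N_PER_CLASS, geom, COHORT_SEED):
        window = delimit_window(sim_pass.frames, cfg)
        arrival_errors.append(abs(window.start_frame - sim_pass.truth_arrival_frame))
        rows.append(features_from_pass(sim_pass, geom).as_row())
    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    features.index.name = "fillet_id"
    assert not features.isna().any().any(), "cohort feature extraction produced NaNs"
    return {"features": features, "arrival_errors": np.asarray(arrival_errors)}
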