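import numpy as np
import pytest

from vesselmorph.efa import EllipticalFourierAnalysis
from vesselmorph.outline import mirror_to_outline, resample_profile, smooth_profile
from vesselmorph.synthetic import (
    default_study_config,
    default_vessel_types,
    make_profile,
    simulate_study,
)


@pytest.fixture(scope="session")
def vessel_profile():
    """A typical closed-form vessel profile (the default final form)."""
    return make_profile(default_vessel_types()[0][1], n_points=256)


@pytest.fixture(scope="session")
def vessel_outline(vessel_profile):
    return mirror_to_outline(vessel_profile)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study used across tests (fast to analyse)."""
    return simulate_study(
        default_study_config(seed=7, n_trials_per_type=3, profile_points=96)
    )


@pytest.fixture(scope="session")
def study_coeffs(small_study):
    """Normalized coefficient vectors for every stage outline of the study,
    keyed by (trial_id, gesture_index)."""
    efa = EllipticalFourierAnalysis(n_harmonics=12).fit(None)
    out = {}
    for tr in small_study.trials:
        for st in tr.stages:
            p = smooth_profile(resample_profile(st.profile, 96))
            out[(tr.trial_id, st.gesture_index)] = efa.transform_one(
                mirror_to_outline(p)
            ).flatten()
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
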