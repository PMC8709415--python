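import numpy as np
import pytest

import actiprofiles as ap


@pytest.fixture(scope="session")
def fast_config():
    """Small, coarse-epoch cohort configuration for quick pipeline tests."""
    return ap.CohortConfig(
        n_per_archetype=3, epoch_seconds=300, noise_sd=5.0, seed=11,
        n_outliers_high_mean=2, n_low_wear=2)


@pytest.fixture(scope="session")
def fast_cohort(fast_config):
    return ap.simulate_cohort(fast_config)


@pytest.fixture(scope="session")
def templates():
    return {name: ap.make_archetype_template(name) for name in ap.ARCHETYPE_NAMES}


@pytest.fixture(scope="session")
def noisy_profiles():
    """A labelled profile matrix from a moderately noisy coarse-epoch cohort."""
    config = ap.CohortConfig(
        n_per_archetype=12, epoch_seconds=300, noise_sd=3.0, seed=5,
        n_outliers_high_mean=0, n_low_wear=0)
    profiles, _ = ap.preprocess_cohort(s for s, _ in ap.iter_cohort(config))
    truth = {row["participant_id"]: row["archetype"]
             for _, row in ap.synth_cohort._plan_cohort(config).iterrows()}
    X = np.stack([p.hours for p in profiles])
    labels = np.array([truth[p.participant_id] for p in profiles])
    return X, labels
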