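import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lab6():
    """Fitted lab-phase pipeline on the 6-class synthetic study (cached).

    2 stationary + 3 walking-like (one duplicated pair) + 1 running-like
    profile, 120 train + 120 test windows per class, wavelet selector +
    10-component PCA feature space.
    """
    from helpers import lab6_profiles, make_lab_windows
    from wristhar.pipeline import fit_feature_space, windows_to_sequences

    profiles, ids = lab6_profiles()
    train = make_lab_windows(profiles, ids, seed=1)
    test = make_lab_windows(profiles, ids, seed=2)
    space = fit_feature_space(train, n_coeffs=20, pca_dims=10)
    x_train, y_train = windows_to_sequences(train, space)
    x_test, y_test = windows_to_sequences(test, space)
    return {
        "profiles": profiles,
        "ids": ids,
        "space": space,
        "train": (x_train, y_train),
        "test": (x_test, y_test),
    }
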