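import warnings

import pytest

from medvigil.synth import SimConfig, generate_population


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # constant-covariate drops are routine on small synthetic corpora
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="dropping constant covariates")
        yield


@pytest.fixture(scope="session")
def small_population():
    """A small but structurally complete corpus shared by read-only tests."""
    cfg = SimConfig(n_treatment=60, n_control=60, posts_per_user_mean=30.0, seed=42)
    return cfg, generate_population(cfg)
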