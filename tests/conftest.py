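import pytest
from hypothesis import settings

from nirsvft import Paradigm, default_montage
from nirsvft.synth import (
    ArtifactSpec,
    NoiseSpec,
    default_sim_config,
)

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def paradigm():
    return Paradigm()


@pytest.fixture(scope="session")
def quiet_cfg(montage):
    """Noise-free, artifact-free configuration (signal model only)."""
    return default_sim_config(
        seed=11,
        n_per_group=2,
        montage=montage,
        noise=NoiseSpec(white_sd=0.0, ar1_coef=0.0, oscillations=(),
                        drift_slope_sd=0.0, slow_cutoff_hz=0.08),
        artifact=ArtifactSpec(0.0, 0.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One small full cohort, shared across tests (recordings + truth)."""
    from nirsvft.synth import simulate_cohort

    return simulate_cohort(default_sim_config(seed=21, n_per_group=3))
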