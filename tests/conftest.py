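import numpy as np
import pytest

from mcbacksim import MediaOptics, SimulationConfig


@pytest.fixture
def phantom_iso() -> MediaOptics:
    """Solid reference phantom, isotropic parameterization (g = 0)."""
    return MediaOptics(mu_a=0.1056, mu_s=2.529, g=0.0, n=1.35)


@pytest.fixture
def phantom_aniso() -> MediaOptics:
    """Same phantom, forward-scattering parameterization with equal mu_s'."""
    return MediaOptics(mu_a=0.1056, mu_s=25.29, g=0.9, n=1.35)


@pytest.fixture
def apple() -> MediaOptics:
    """Apple tissue at 670 nm."""
    return MediaOptics(mu_a=0.63, mu_s=30.0, g=0.0, n=1.4)


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """Fast configuration for unit tests."""
    return SimulationConfig(
        n_photons=2000, beam_radius=0.05, limit=1e-9, obs_radius=3.0, rpx=0.05, seed=42
    )


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    from scipy import stats

    return float(stats.pearsonr(a, b).statistic)
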