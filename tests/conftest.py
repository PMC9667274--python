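import pytest

from gompertz_sde import ColoredNoiseParams, GompertzParams, WhiteNoiseParams


@pytest.fixture
def gp():
    """The benchmark rates used throughout the transition-time studies."""
    return GompertzParams(alpha=0.25, beta=0.2)


@pytest.fixture
def gp_growth():
    """Fast-growth / slow-death rates used in the density sweeps."""
    return GompertzParams(alpha=0.3, beta=0.1)


@pytest.fixture
def wp():
    """White-noise intensities of the stationary-density sweeps."""
    return WhiteNoiseParams(D1=0.25, Q=0.15, lambda1=0.2)


@pytest.fixture
def cp_bench():
    """Colored-noise set used for first-passage and moment benchmarks."""
    return ColoredNoiseParams(D2=0.35, Q=0.15, lambda2=0.1, tau=0.2)


@pytest.fixture
def cp_overlay():
    """Colored-noise set of the simulation-overlay density comparison."""
    return ColoredNoiseParams(D2=0.35, Q=0.15, lambda2=0.2, tau=0.1)
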