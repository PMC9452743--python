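import pytest

from cardiocea.model import baseline_model, sweep_model


@pytest.fixture(scope="session")
def baseline():
    """Reference comparison: 50-year-old, 5 Gy photon vs 0.5 Gy proton,
    each arm calibrated to its own cumulative incidence targets."""
    return baseline_model()


@pytest.fixture(scope="session")
def sweep():
    """Zero-dose-calibrated model for dose / risk-multiplier sweeps."""
    return sweep_model()
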