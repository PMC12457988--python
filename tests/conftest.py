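import pytest

import avypop as ap


@pytest.fixture(scope="session")
def ref_fit():
    """Survival fit at the published coefficient values."""
    return ap.reference_fit()


@pytest.fixture(scope="session")
def calibrated(ref_fit):
    """Vital-rate schedule calibrated so deterministic λ(m=0.07) = 1.015."""
    return ap.calibrate_baseline(ref_fit)


@pytest.fixture(scope="session")
def event_series():
    """Fixed 43-year avalanche-mortality event series."""
    return ap.reference_event_series()
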