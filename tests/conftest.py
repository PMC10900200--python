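import numpy as np
import pytest
from hypothesis import settings

import glycobalance as gb

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: study concentrations: 1 mM amine, 0.5 mM aldehyde
A0, L0 = 1e-3, 5e-4


@pytest.fixture
def reference_rates() -> gb.RateConstants:
    """A mid-regime rate set whose closed-form ratios are (keq=4, initial=2)."""
    return gb.RateConstants(
        k1=10.0, k_m1=0.002, k1Z=0.02, k_m1Z=0.002, k1E=0.01, k_m1E=0.004
    )


@pytest.fixture
def loads() -> tuple[float, float]:
    return A0, L0
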