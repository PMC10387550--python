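import numpy as np
import pytest

from aquaresp import synthetic as sy


@pytest.fixture
def setup21():
    """Study-mean chamber/fish at the 21 degC control temperature."""
    return sy.default_setup(temperature=21.0)


@pytest.fixture
def small_respirometry():
    """A short noise-free respirometry trace plus its ground truth."""
    return sy.gen_respirometry_trace(n_rest_cycles=10, n_chase_cycles=3, seed=1)


def benson_krause_o2_mg_l(temp_c: float, salinity_ppt: float) -> float:
    """Independent solubility oracle: Benson & Krause air-saturation fit.

    Distinct published fit (the APHA/USGS dissolved-oxygen formula) used
    only to cross-check the package's solubility function.
    """
    T = temp_c + 273.15
    ln_do = (
        -139.34411
        + 1.575701e5 / T
        - 6.642308e7 / T**2
        + 1.243800e10 / T**3
        - 8.621949e11 / T**4
    )
    chl = salinity_ppt / 1.80655
    ln_do -= chl * (3.1929e-2 - 19.428 / T + 3.8673e3 / T**2)
    return float(np.exp(ln_do))
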