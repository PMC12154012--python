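import numpy as np
import pytest

from inactikin import WeibullFamily

# Published Salmonella enteritidis thermal-resistance set: log-logistic
# secondary b(T) with k = 0.348 1/degC, Tc = 66.34 degC, shape n = 0.545.
SALMONELLA = {"k": 0.348, "Tc": 66.34, "n": 0.545}

# Published Bacillus sporothermodurans IC4 (McIlvaine pH5) Bigelow set:
# z = 7.20 degC, delta_ref = 1.36 min, n = 1.25.  The reference
# temperature is a free convention; 120 degC (mid-range of the study's
# isothermal temperatures) is used throughout.
BSPORO = {"delta_ref": 1.36, "Tref": 120.0, "z": 7.20, "n": 1.25}


@pytest.fixture(scope="session")
def salmonella_family() -> WeibullFamily:
    return WeibullFamily.from_log_logistic(**SALMONELLA)


@pytest.fixture(scope="session")
def bsporo_family() -> WeibullFamily:
    return WeibullFamily.from_bigelow(**BSPORO)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
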