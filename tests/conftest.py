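import numpy as np
import pytest

from gelcomp import BindingSystem, NetworkSpec

# boronate-ester gel formulation: 10% w/v tetra-arm PEG, ~38 mM end
# groups of each type, strongest diol competitor
KA_XL_BORONATE = 2200.0
KA_XL_BORONATE_SD = 100.0
KA_C_STRONG = 6700.0
KA_C_STRONG_SD = 600.0
KA_C_WEAK = 6.2
N_XL = 0.038

# hydrazone chemistry: benzyl-hydrazone cross-link vs methylhydrazine
KA_XL_HYDRAZONE = 1350.0
KA_C_MEHZ = 510.0


@pytest.fixture
def boronate_binding() -> BindingSystem:
    return BindingSystem(ka_xl=KA_XL_BORONATE, ka_c=KA_C_STRONG,
                         ka_xl_sd=KA_XL_BORONATE_SD, ka_c_sd=KA_C_STRONG_SD)


@pytest.fixture
def network() -> NetworkSpec:
    return NetworkSpec(n_xl=N_XL)


@pytest.fixture
def titration_grid() -> np.ndarray:
    return np.array([0.0, 2.5e-3, 5e-3, 7.5e-3, 10e-3, 15e-3])
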