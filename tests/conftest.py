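import numpy as np
import pytest

import sabrekin as sk


@pytest.fixture
def py280_speciation():
    """Pyridine-like composition: 4 mM catalyst, 40 mM substrate, ratio 7.46."""
    K = sk.equilibrium_constant_from_ratio(0.004, 0.040, 7.46)
    return sk.steady_state_concentrations(
        sk.ChemicalSystem(C0=0.004, S0=0.040, K=K, T=280.0, substrate="Py")
    )


@pytest.fixture
def spec_a_py280(py280_speciation):
    return sk.ExchangeModelSpec(
        "A",
        sk.RateConstants(k_d=1.9),
        R_bound=0.5,
        R_free=0.125,
        speciation=py280_speciation,
    )


def make_spec_b(k_d=1.9, ratio_r=7.46, R_bound=0.5, R_free=0.125):
    return sk.ExchangeModelSpec(
        "B", sk.RateConstants(k_d=k_d), R_bound=R_bound, R_free=R_free, ratio_r=ratio_r
    )


@pytest.fixture
def spec_b_py280():
    return make_spec_b()


def noiseless_sexsy(spec, n=40):
    return sk.simulate_sexsy(
        sk.SimulationConfig(spec=spec, d_mix=np.geomspace(0.02, 12.0, n), noise_sd=0.0)
    )
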