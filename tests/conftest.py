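import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from lactodyn import (
    ExperimentDesign,
    ParamVector,
    RateParamsBrown,
    RateParamsMM,
    SystemState,
    scfe,
)

hypothesis_settings.register_profile("repro", derandomize=True)
hypothesis_settings.load_profile("repro")

# Published identified optima of the two mechanisms (fixed inputs)
TABLE1_OPT = {"kd": 0.09647381, "a": 0.9180534, "m": 16.2354,
              "tau_min": 4.607475, "lambda_m0": 0.06818154, "K_kohl": 1e-10}
TABLE2_OPT = {"k1": 0.08717502, "k_m1": 0.1048326, "k2": 0.1220813,
              "tau1": 15.69849, "tau2": 5.357829,
              "lambda_m0": 0.2323843, "K_kohl": 1.171464e-05}
NE_BAR = 1.139071  # mM, total enzyme


@pytest.fixture(scope="session")
def table2_rates() -> RateParamsMM:
    return RateParamsMM(k1=TABLE2_OPT["k1"], k_m1=TABLE2_OPT["k_m1"],
                        k2=TABLE2_OPT["k2"], tau1=TABLE2_OPT["tau1"],
                        tau2=TABLE2_OPT["tau2"])


@pytest.fixture(scope="session")
def table1_rates() -> RateParamsBrown:
    return RateParamsBrown(kd=TABLE1_OPT["kd"], a=TABLE1_OPT["a"],
                           m=TABLE1_OPT["m"], tau_min=TABLE1_OPT["tau_min"])


@pytest.fixture(scope="session")
def table2_pv() -> ParamVector:
    return ParamVector.from_dict("mm2d", TABLE2_OPT)


@pytest.fixture(scope="session")
def equilibrium():
    return scfe(NE_BAR)


@pytest.fixture(scope="session")
def sweep_init() -> SystemState:
    return SystemState(nS=1.0, nE=NE_BAR, nC=1e-9, nP=1e-9)


@pytest.fixture
def small_design() -> ExperimentDesign:
    """Short, two-concentration design for fast fitting tests."""
    return ExperimentDesign(nS0_list=(0.5, 1.0), duration=40.0,
                            sampling_interval=2.0, noise_sd=0.0, seed=7)
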