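import numpy as np
import pytest

from bnyg import PhaseParams, PhysicalParams, infer_liquid_phase

#: Worked-application inputs: 22 °C, 100× bulk-water viscosity, 50 nm bead,
#: measured Davg = 0.40 μm²/s, critical time 4 s.
PAPER_CONFIG = {
    "physical": {
        "temperature_C": 22.0,
        "water_viscosity_mPas": 1.0,
        "viscosity_multiplier": 100.0,
        "radius_nm": 50.0,
    },
    "phase": {"Davg_um2s": 0.40, "tc_s": 4.0, "Z_G": 1.0},
}


@pytest.fixture(scope="session")
def paper_physical() -> PhysicalParams:
    return PhysicalParams.from_config(PAPER_CONFIG["physical"])


@pytest.fixture(scope="session")
def paper_phase() -> PhaseParams:
    # The worked chain reports D to two significant figures before the
    # inversion; the reported DeffL/Z_L roundings follow from that value.
    return infer_liquid_phase(0.40, 0.014, Z_G=1.0, tc=4.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
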