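import pytest

from jawmorph import SimulationConfig, balanced_config, simulate_assemblage
from jawmorph.io import RawJawMeasurements


@pytest.fixture(scope="session")
def toy_measurements() -> RawJawMeasurements:
    """A hand-checkable jaw: every lever arm is round-number arithmetic."""
    return RawJawMeasurements(ML=1000, ASD=150, MSL=300, MSD=80, TRL=550,
                              CPD=120, RPL=100, maL=200, LCH=40,
                              DLT=450, ILc=150)


@pytest.fixture(scope="session")
def assemblage47():
    """Default-composition synthetic assemblage (47 specimens, 25 OCF/22 KCF)."""
    return simulate_assemblage(SimulationConfig(seed=20240515))


@pytest.fixture(scope="session")
def balanced30():
    """Balanced six-guild assemblage, 5 specimens per guild."""
    return simulate_assemblage(balanced_config(seed=11, n_per_guild=5))
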