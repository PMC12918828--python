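import numpy as np
import pytest

from bbsoptics import synth
from bbsoptics.tissue_mc import FluorSimConfig


@pytest.fixture(scope="session")
def tpbbs():
    return synth.make_bbs("TpBBS")


@pytest.fixture(scope="session")
def tpbbs_emission(tpbbs):
    return tpbbs.emission.as_spectrum(np.arange(600.0, 901.0))


@pytest.fixture
def small_mc_config():
    """5-nm grid, small photon budget: fast but resolves peak positions."""
    return FluorSimConfig(
        wavelengths=np.arange(650.0, 821.0, 5.0),
        photons_per_wavelength=20_000,
        seed=11,
    )
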