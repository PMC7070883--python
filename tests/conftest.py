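import numpy as np
import pytest

from polir import decomposition as dc
from polir import synthetic
from polir.spectra import SpectralWindow


@pytest.fixture(scope="session")
def noiseless_fixture():
    """Canonical four-band CaChR1-like surface without noise."""
    return synthetic.cachr1_fixture(noise_sd=0.0)


@pytest.fixture()
def model_spec():
    """ModelSpec matching the canonical fixture's generating parameters."""
    return dc.ModelSpec(
        bands=synthetic.cachr1_bands(),
        kin=synthetic.cachr1_kinetics(),
        fit_window=SpectralWindow(1655.0, 1750.0),
    )


def perturbed_spec(seed: int) -> dc.ModelSpec:
    """ModelSpec with initial guesses jittered by the recovery protocol."""
    rng = np.random.default_rng(seed)
    bands, kin = synthetic.perturbed(
        synthetic.cachr1_bands(), synthetic.cachr1_kinetics(), rng
    )
    return dc.ModelSpec(bands=bands, kin=kin, fit_window=SpectralWindow(1655.0, 1750.0))
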