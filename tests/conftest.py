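import numpy as np
import pytest

from fretrla.efficiency import ForsterParams
from fretrla.fixtures import (
    SyntheticDyeSpec,
    SyntheticSystemSpec,
    single_rotamer_library,
    synth_dye_ensemble,
    synth_rod_system,
)
from fretrla.libgen import build_library
from fretrla.placement import EnergyConfig, LabeledSite


@pytest.fixture(scope="session")
def dye_ensemble():
    """Seeded 3-state dye ensemble (0.6/0.3/0.1, T=2000, noise sd 8°)."""
    return synth_dye_ensemble(SyntheticDyeSpec())


@pytest.fixture(scope="session")
def small_library(dye_ensemble):
    ens, _ = dye_ensemble
    return build_library(ens, cutoff=30, name="probe small", cutoff_class="small")


@pytest.fixture(scope="session")
def rod_ensemble():
    """Rigid two-site rod, 50 Å CA-CA separation, 5 identical frames."""
    return synth_rod_system(SyntheticSystemSpec(separation=50.0, n_frames=5))


@pytest.fixture
def energy_config():
    return EnergyConfig()


@pytest.fixture(scope="session")
def sites():
    return LabeledSite(1, "A"), LabeledSite(2, "A")


@pytest.fixture
def anchor_libraries():
    """One-rotamer donor/acceptor libraries engineered so that the pair
    geometry gives exactly κ² = 2/3 and r = the CA-CA separation."""
    donor = single_rotamer_library(
        "anchor-donor", center_offset=(0.0, -3.0, 3.0), dipole_direction=(1.0, 0.0, 0.0)
    )
    acceptor = single_rotamer_library(
        "anchor-acceptor",
        center_offset=(0.0, -3.0, 3.0),
        dipole_direction=(np.sqrt(2.0 / 3.0), np.sqrt(1.0 / 3.0), 0.0),
    )
    return donor, acceptor


@pytest.fixture
def fixed_r0_50():
    return ForsterParams(mode="fixed", r0=50.0)
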