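import numpy as np
import pytest

from dnafret.photophysics import DyeSpecies, gaussian_spectrum


def make_species(
    name,
    abs_center,
    em_center,
    quantum_yield=0.9,
    lifetime_ns=1.0,
    sigma=15.0,
    eps_max=1e5,
    span=3.0,
):
    """Synthetic test dye with narrow truncated Gaussian bands."""
    return DyeSpecies(
        name,
        gaussian_spectrum(abs_center, sigma, eps_max, span=span),
        gaussian_spectrum(em_center, sigma, 1.0, span=span),
        quantum_yield=quantum_yield,
        lifetime_ns=lifetime_ns,
    )


@pytest.fixture
def disjoint_pair():
    """Donor/acceptor with spectrally disjoint bands: the only nonzero
    coupling is a forward R0 override, so there is no back transfer."""
    donor = make_species("D", 350, 420, quantum_yield=0.9, lifetime_ns=1.0)
    acceptor = make_species("A", 650, 720, quantum_yield=0.5, lifetime_ns=2.0)
    return {"D": donor, "A": acceptor}


@pytest.fixture
def disjoint_chain():
    """Three-dye ladder (donor, bridge, acceptor) with pairwise-disjoint
    emission/absorption so all couplings come from explicit R0 overrides
    and no back transfer exists."""
    return {
        "D": make_species("D", 330, 375, quantum_yield=0.8, lifetime_ns=1.0),
        "B": make_species("B", 500, 540, quantum_yield=0.6, lifetime_ns=0.8),
        "A": make_species("A", 660, 710, quantum_yield=0.4, lifetime_ns=2.5),
    }
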