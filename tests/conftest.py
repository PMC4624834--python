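import numpy as np
import pytest

import iovdesign as iv


@pytest.fixture(scope="session")
def onecomp():
    return iv.onecomp_fixture(dose_scale=500.0)


@pytest.fixture(scope="session")
def onecomp_combined():
    return iv.onecomp_fixture(error="combined", dose_scale=500.0)


@pytest.fixture(scope="session")
def colistin():
    return iv.colistin_fixture()


@pytest.fixture()
def toy():
    """Canonical linear toy: y = eta + kappa_occ + eps, 2 occasions x 2 samples."""
    fixture = iv.linear_toy(omega=[[1.0]], pi=[[1.0]], sigma=1.0, m=2, tau=1.0)
    design = iv.Design(np.array([0.1, 0.5, 1.1, 1.5]), np.zeros(4, int))
    return fixture, design


def toy_realization(fixture, eta=None, kappas=None):
    r0 = fixture.zero_realization()
    return iv.IndividualRealization(
        r0.eta if eta is None else eta,
        r0.kappas if kappas is None else kappas,
    )
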