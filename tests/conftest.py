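"""Shared fixtures: the compiled reference model and its basal state.

Session scope keeps the sympy->lambdify compilation and the reference
dose-response (both reused by many tests) to a single computation.
"""

import numpy as np
import pytest

import spornet as sn


@pytest.fixture(scope="session")
def model():
    return sn.build_reference_network()


@pytest.fixture(scope="session")
def basal(model):
    return sn.pre_equilibrate(model)


@pytest.fixture(scope="session")
def ref_dose(model):
    """Reference IPTG dose-response (0..20, 21 points) of the intact model."""
    return sn.dose_response(model, "IPTG")


@pytest.fixture(scope="session")
def random_states():
    """100 reproducible random nonnegative states spanning several decades."""
    rng = np.random.default_rng(46210)
    mags = rng.uniform(-2, 5, size=(100, len(sn.FORMS)))
    return 10.0 ** mags * (rng.random((100, len(sn.FORMS))) > 0.1)
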