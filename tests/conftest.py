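import pytest

from imkdose import load_reference_params, make_acute


@pytest.fixture(scope="session")
def ref_params():
    return load_reference_params()


@pytest.fixture(scope="session")
def hlec(ref_params):
    return ref_params["HLEC"]


@pytest.fixture(scope="session")
def wi38(ref_params):
    return ref_params["WI-38"]


@pytest.fixture(scope="session")
def hlec_consistent(hlec):
    """HLEC parameters with (alpha0, beta0) recomputed from (a, b) so the
    kinetic and survival routes agree to machine precision."""
    return hlec.with_consistent_lq()


@pytest.fixture(scope="session")
def acute_1gy():
    return make_acute(1.0, 1.82)
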