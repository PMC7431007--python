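import warnings

import pytest

from histbrace.pipeline import load_reference_systems


@pytest.fixture(scope="session")
def reference_systems():
    """The packaged spin-Hamiltonian parameter sets, keyed by label."""
    return load_reference_systems()


@pytest.fixture(scope="session")
def free_x(reference_systems):
    """Substrate-free X-band ¹⁴N system (rhombic, five-coordinate site)."""
    return reference_systems["free_X_14N"]


@pytest.fixture(scope="session")
def bound_x(reference_systems):
    """Chitin-bound X-band ¹⁴N system (axial, large |A3|)."""
    return reference_systems["chitin_X_14N"]


@pytest.fixture(autouse=True)
def _silence_plausibility_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
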