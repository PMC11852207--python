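import pytest

from shufflon.design import default_design, render_reference_set
from shufflon.classify import ExhaustiveDecoder, build_marker_index

SEED = 0


@pytest.fixture(scope="session")
def design5():
    return default_design(seed=SEED)


@pytest.fixture(scope="session")
def design1():
    return default_design(seed=SEED, module_lengths=(143,))


@pytest.fixture(scope="session")
def reference_set(design5):
    return render_reference_set(design5)


@pytest.fixture(scope="session")
def marker_index(design5):
    return build_marker_index(design5)


@pytest.fixture(scope="session")
def exhaustive_decoder(design5, reference_set):
    return ExhaustiveDecoder(design5, reference_set)
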