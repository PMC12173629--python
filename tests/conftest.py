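import pytest

from rtcompare import ObserverSimulator, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def reference(phantom_spec):
    """The default deterministic phantom, built once for the whole run."""
    return make_phantom(phantom_spec)


@pytest.fixture(scope="session")
def breast_simulator(reference):
    """Observer simulator restricted to CTV-breast (cheap for large cohorts)."""
    return ObserverSimulator(reference, labels=("CTV-breast",))
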