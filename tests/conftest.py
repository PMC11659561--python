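import pytest

from drdtrial import SimulationConfig, build_reference_dataset, generate_trial, load_paper_eyes


@pytest.fixture(scope="session")
def reference_ds():
    """The 1073-eye dataset reconstructed from the published counts."""
    return build_reference_dataset()


@pytest.fixture(scope="session")
def packaged_ds():
    """The shipped paper_eyes.csv fixture."""
    return load_paper_eyes()


@pytest.fixture(scope="session")
def small_trial():
    """A modest synthetic trial with AI outputs, for unit-level checks."""
    return generate_trial(SimulationConfig(n_participants=800, seed=11))
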