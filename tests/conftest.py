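import pytest

from metaboswitch.synthetic import generate_mirror_dataset


@pytest.fixture(scope="session")
def mirror():
    """One mirror-of-study dataset shared across tests (fixed seed)."""
    return generate_mirror_dataset(seed=11)
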