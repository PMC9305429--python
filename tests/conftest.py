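import pytest

from lavauth import (
    generate_fixture_set,
    load_chemokey,
    load_compound_library,
    zero_noise_config,
)
from lavauth.pipeline import amplify_panel


@pytest.fixture(scope="session")
def library():
    return load_compound_library()


@pytest.fixture(scope="session")
def key():
    return load_chemokey()


@pytest.fixture(scope="session")
def zero_fixtures():
    """Noise-free synthetic panel shared across the suite (seed 7)."""
    return generate_fixture_set(zero_noise_config(seed=7))


@pytest.fixture(scope="session")
def amplicons(zero_fixtures):
    """marker -> taxon -> amplicon sequence, from the noise-free references."""
    return {
        marker: amplify_panel(refs, marker)
        for marker, refs in zero_fixtures.references.items()
    }
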