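import random

import pytest

from glycan_babel.fixtures import build_corpus


@pytest.fixture(scope="session")
def corpus():
    """The full programmatically generated fixture corpus."""
    return build_corpus(seed=7, dialect_variants=2)


@pytest.fixture()
def rng():
    return random.Random(12345)
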