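import numpy as np
import pytest

from shortprot.synthetic import GeneratorConfig, generate_proteome


@pytest.fixture(scope="session")
def small_proteome():
    """A small labeled proteome with planted cassettes (60 short, 120 long)."""
    cfg = GeneratorConfig(n_short=60, n_long=120, seed=7)
    records, labels, truth = generate_proteome(cfg)
    return records, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))
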