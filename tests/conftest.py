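import numpy as np
import pytest

import peptiprospect as pp


@pytest.fixture(scope="session")
def biopep_specs():
    return pp.compile_ruleset("BIOPEP")


@pytest.fixture(scope="session")
def expasy_specs():
    return pp.compile_ruleset("EXPASY")


@pytest.fixture(scope="session")
def longlist():
    return pp.load_fixture("table2_longlist")


@pytest.fixture(scope="session")
def score_table():
    return pp.load_fixture("table3_scores")


@pytest.fixture(scope="session")
def ace_bindings():
    return pp.load_fixture("table4_ace_bindings")


@pytest.fixture(scope="session")
def dppiv_bindings():
    return pp.load_fixture("table5_dppiv_bindings")


@pytest.fixture(scope="session")
def class_rules():
    return {rule.name: rule for rule in pp.default_rules()}


def random_sequences(seed, n, min_len=2, max_len=30):
    """Seeded random peptide/protein sequences over the canonical alphabet."""
    rng = np.random.default_rng(seed)
    alphabet = sorted(pp.digestion.AMINO_ACIDS)
    return [
        "".join(rng.choice(alphabet, size=int(rng.integers(min_len, max_len + 1))))
        for _ in range(n)
    ]
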