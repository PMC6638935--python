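import numpy as np
import pytest

import squigglesim as sq


@pytest.fixture(scope="session")
def small_fixture():
    """Synthetic (pore model, gold) pair with 400 gold events."""
    return sq.make_fixture(5, 404, 5)


@pytest.fixture(scope="session")
def tiny_model():
    """Minimal hand-built 3-mer model for lookup tests."""
    import itertools

    levels = {
        "".join(p): 40.0 + 3.0 * i
        for i, p in enumerate(itertools.product("ACGT", repeat=3))
    }
    levels.update({"ACG": 50.0, "CGT": 60.0, "GTA": 70.0})
    return sq.KmerModel(k=3, levels=levels)
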