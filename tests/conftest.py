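import numpy as np
import pytest
from hypothesis import settings

from rdnachip import synthetic

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

# toy design shared by alignment/signal tests: 3 identical 2 kb copies in
# 8 kb of unique background; 30 bp reads give a 10 bp pigeonhole seed
TOY_READ_LENGTH = 30
TOY_K = 10


@pytest.fixture(scope="session")
def toy_genome():
    spec = synthetic.RepeatGenomeSpec(
        unit_length=2000,
        n_copies=3,
        background_length=8000,
        gc_fraction=0.5,
        seed=11,
        guard_k=TOY_K,
    )
    return synthetic.make_genome(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


def random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, n, p=p)])
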