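import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

import seealign as sa
from seealign.simulate import simulate_reference

SMALL_PRIME = 10007
DESK_PRIME = 16_777_213  # 2^24 - 3; load factor ~1/16 on a 1 Mb reference


@pytest.fixture(scope="session")
def small_cfg():
    return sa.validate_config(sa.Config(k=8, buckets=SMALL_PRIME))


@pytest.fixture(scope="session")
def ref_100k():
    """A 100 kb random reference with its index (k=32) and embedding tables."""
    seq = simulate_reference(100_000, 20_240)
    cfg = sa.validate_config(sa.Config(buckets=1_000_003))
    reference = sa.Reference([("sim_ref", seq)])
    idx = sa.build_index(reference, cfg)
    F = sa.make_embedding_functions(cfg.rng_seed)
    return seq, reference, idx, F, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def ref_10k():
    """A 10 kb reference indexed at a very low load factor (few collisions)."""
    seq = simulate_reference(10_000, 31)
    cfg = sa.validate_config(sa.Config(buckets=DESK_PRIME))
    reference = sa.Reference([("sim_ref", seq)])
    idx = sa.build_index(reference, cfg)
    F = sa.make_embedding_functions(cfg.rng_seed)
    return seq, reference, idx, F, cfg
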