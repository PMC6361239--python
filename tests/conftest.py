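import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from akid import build_profile, fixtures


@pytest.fixture(scope="session")
def family_hmm():
    """Profile built from a well-conserved synthetic kinase-family MSA."""
    rows = fixtures.gen_family_msa(20, 40, mutation_rate=0.05, indel_rate=0.0, seed=7)
    return build_profile(rows)


@pytest.fixture(scope="session")
def toy_hmm():
    """Tiny 3-column profile for hand-checkable alignments."""
    return build_profile(["ACD", "A-D", "ACD"], occupancy_threshold=0.5)


def random_small_hmm(seed):
    """A random small profile (2-4 match columns) or None if degenerate."""
    rng = np.random.default_rng(seed)
    ncols = int(rng.integers(2, 5))
    rows = fixtures.gen_family_msa(
        4, ncols, mutation_rate=0.3, indel_rate=0.15, seed=int(rng.integers(100000))
    )
    try:
        return build_profile(rows, 0.5)
    except ValueError:
        return None
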