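import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tetrap import invasion_sim as sim

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def standard_layout():
    """Five 32.4-Mb arms, 850-kb terminal clusters, r = 4 cM/Mb."""
    return sim.standard_layout()


@pytest.fixture(scope="session")
def small_layout():
    """Tiny two-arm genome for fast unit tests."""
    return sim.build_genome([1_000_000, 500_000], 100_000, 4.0)


def make_reads(records, reference="PPI251"):
    """Read table from (pos5, strand, length, count) tuples."""
    return pd.DataFrame(
        [
            {
                "reference": reference,
                "pos5": p,
                "strand": s,
                "length": ln,
                "count": c,
            }
            for p, s, ln, c in records
        ]
    )
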