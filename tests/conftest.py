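import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_alignment():
    from microdelim.io import Alignment

    return Alignment(
        ids=("s1", "s2", "s3", "s4"),
        seqs=("ACGTACGTAC", "ACGTACGTAC", "ACGTACGTTT", "TTTTACGTTT"),
    )


@pytest.fixture
def balanced_tree():
    from microdelim.io import UltrametricTree

    return UltrametricTree.from_newick("((A:1,B:1):2,(C:1,D:1):2);")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
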