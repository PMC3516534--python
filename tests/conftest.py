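import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_interactome(edges, n_evidence=None):
    """Small interactome from (a, b) pairs; optional per-pair evidence counts."""
    from crosstalknet.interactome import EvidenceEdge, Interactome
    from crosstalknet.io_formats import canonical_pair

    pairs = {}
    for i, (a, b) in enumerate(edges):
        pair = canonical_pair(a, b)
        count = 1 if n_evidence is None else n_evidence[i]
        pairs[pair] = [
            EvidenceEdge(pair=pair, source="COMPLEX", provenance=f"C{i}_{j}")
            for j in range(count)
        ]
    return Interactome(pairs)
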