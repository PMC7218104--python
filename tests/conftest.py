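import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from consdesign.alignment_io import AlignedSequence, Alignment

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_alignment(rows, query_id=None, ids=None):
    """Build an Alignment from plain gapped strings (test helper)."""
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return Alignment(
        sequences=[AlignedSequence(i, i, r) for i, r in zip(ids, rows)],
        query_id=query_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def tiny_alignment():
    """4 x 10 alignment with a flagged, partially gapped query."""
    return make_alignment(
        [
            "ACDEF-GHIK",
            "ACDEFMGHIK",
            "ACDEYMGHIK",
            "SCDEFMGH-K",
        ],
        query_id="s0",
    )
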