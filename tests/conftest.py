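import numpy as np
import pytest

from poremeth.event_hmm import Event, EventSequence
from poremeth.pore_model import synthetic_pore_model


@pytest.fixture(scope="session")
def toy_model():
    """Synthetic 3-mer pore model (64 entries, single components)."""
    return synthetic_pore_model(3)


@pytest.fixture(scope="session")
def toy_model6():
    """Synthetic 6-mer pore model (4096 entries)."""
    return synthetic_pore_model(6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_events(means, start=0):
    """Event sequence from raw pA means, labelled consecutively."""
    return EventSequence(
        read_id="t",
        strand="+",
        events=[Event(m, ref_kmer_index=start + i) for i, m in enumerate(means)],
        ref_start=start,
    )
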