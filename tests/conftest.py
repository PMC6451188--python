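import numpy as np
import pytest

from svchrom import GenomeLayout, Interval, SVRecord, SegmentationTrack, WorldConfig, generate_world


@pytest.fixture
def tiny_layout():
    return GenomeLayout((("A", 100), ("B", 50)))


@pytest.fixture(scope="session")
def default_world():
    """One fully-biased synthetic world shared by read-only tests."""
    return generate_world(WorldConfig(seed=1))


@pytest.fixture
def half_track():
    """A 100+50 bp genome whose first chromosome is half A1, half B3."""
    return SegmentationTrack(
        [
            (Interval("A", 0, 50), "A1"),
            (Interval("A", 50, 100), "B3"),
            (Interval("B", 0, 50), "A1"),
        ],
        label_set=("A1", "B3"),
    )


def make_svs(mech, triples):
    return [SVRecord(Interval(c, s, e), mech) for c, s, e in triples]
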