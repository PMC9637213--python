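import numpy as np
import pytest

from eegcsp.montage import build_grid, default_grid
from eegcsp.records import EEGRecord, Event


def make_record(
    data,
    fs=500.0,
    events=(),
    labels=None,
    group="control",
    subject_id="s00",
):
    """Build a record from raw arrays with minimal ceremony."""
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return EEGRecord(
        subject_id=subject_id,
        group=group,
        channel_labels=tuple(labels),
        fs=fs,
        data=data,
        events=[Event(t, int(s)) for t, s in events],
    )


@pytest.fixture
def toy3_grid():
    """3x3 grid labelled A1..C3 (row letter, column digit)."""
    spec = [
        (f"{row}{col + 1}", r, col)
        for r, row in enumerate("ABC")
        for col in range(3)
    ]
    return build_grid(spec)


@pytest.fixture
def toy5_grid():
    """5x5 grid labelled A1..E5."""
    spec = [
        (f"{row}{col + 1}", r, col)
        for r, row in enumerate("ABCDE")
        for col in range(5)
    ]
    return build_grid(spec)


@pytest.fixture(scope="session")
def grid60():
    return default_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
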