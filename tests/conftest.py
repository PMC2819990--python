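import pytest

from slimsig import SequenceDataset, compute_frequencies


@pytest.fixture
def worked_dataset() -> SequenceDataset:
    """The 4-protein two-letter dataset used throughout as a hand-checkable case."""
    return SequenceDataset.from_strings(["LLLLL", "LLLLL", "LWWLL", "LLLLL"])


@pytest.fixture
def worked_freqs(worked_dataset):
    return compute_frequencies(worked_dataset, "global")
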