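import pytest

from photosens.germdata import GerminationRecord, Treatment


@pytest.fixture
def make_records():
    """Build one species' three-treatment records from (long, equal, short) counts."""

    def _make(long, equal, short, n=30, species="sp"):
        counts = {Treatment.LONG: long, Treatment.EQUAL: equal, Treatment.SHORT: short}
        return [
            GerminationRecord(species, t, n, g) for t, g in counts.items()
        ]

    return _make
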