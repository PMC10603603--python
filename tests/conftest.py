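import numpy as np
import pytest

from xltrigger import Peak, PrecursorInfo, Spectrum, dsso


@pytest.fixture(scope="session")
def xl():
    return dsso()


def make_spectrum(peak_tuples, precursor_mz=600.0, precursor_charge=2, scan_id="scan=1", ms_level=2):
    """Spectrum from (mz, intensity) tuples."""
    return Spectrum(
        scan_id=scan_id,
        ms_level=ms_level,
        peaks=[Peak(mz, it) for mz, it in peak_tuples],
        precursor=PrecursorInfo(mz=precursor_mz, charge=precursor_charge),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
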