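import numpy as np
import pytest

import nirtrace as nt
from nirtrace.spectra import SpectraSet, WavelengthRegions, restrict_to_regions


@pytest.fixture
def tiny_spectra():
    """3 samples x 5 wavelengths with full metadata."""
    wl = np.array([1000.0, 1002.0, 1004.0, 1006.0, 1008.0])
    ab = np.array(
        [
            [0.10, 0.20, 0.30, 0.25, 0.15],
            [0.12, 0.22, 0.33, 0.28, 0.18],
            [0.09, 0.18, 0.27, 0.22, 0.13],
        ]
    )
    return SpectraSet(wl, ab, ["A", "B", "C"], ["X", "X", "Y"], [4.5, 5.0, 5.5])


@pytest.fixture(scope="session")
def study_data():
    """The default synthetic nine-origin study (seed 0), on the working
    1000-1798 nm window."""
    s = nt.generate(nt.default_study_profiles(), nt.default_generator_config(seed=0))
    return restrict_to_regions(s, WavelengthRegions([nt.WORKING_RANGE]))


def grid(start=1000.0, stop=1100.0, step=2.0):
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
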