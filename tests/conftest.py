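import warnings

import pytest

from petrelpop import datasets


@pytest.fixture(scope="session")
def published_marray():
    """The reconstructed ten-year m-array of the shipped CMR dataset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return datasets.cmr_marray()


@pytest.fixture(scope="session")
def brood_table():
    return datasets.brood_patch_table()
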