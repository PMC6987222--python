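import pytest

from neatquant.isoform_quant import RegionModel


@pytest.fixture(scope="session")
def model() -> RegionModel:
    return RegionModel.default()
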