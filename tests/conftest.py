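import pytest

from pmpsugars import io as pio


@pytest.fixture(scope="session")
def reference_ions():
    return pio.load_reference_ions()


@pytest.fixture(scope="session")
def curves():
    return pio.calibration_curves()


@pytest.fixture(scope="session")
def content_matrix():
    return pio.sample_content_matrix()


@pytest.fixture(scope="session")
def s1_contents(content_matrix):
    return content_matrix.loc["S1"].to_dict()
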