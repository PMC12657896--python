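import pytest

from strandcode.codes import build_code


@pytest.fixture(scope="session")
def all_codes():
    return {rid: build_code(rid) for rid in ("1/3", "1/2", "2/3")}


@pytest.fixture(scope="session")
def fixture_payload():
    from strandcode.pipeline import load_text_fixture

    return load_text_fixture()
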