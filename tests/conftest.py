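import pytest

from helixbend import build_ideal_duplex, build_repeat_construct, infer_pairing


@pytest.fixture(scope="session")
def ideal24():
    """24-bp mixed-sequence ideal A-form duplex (two full turns)."""
    return build_ideal_duplex("GCGAUCGAUCGCAUGCAUGCGAUC")


@pytest.fixture(scope="session")
def ideal40():
    return build_ideal_duplex("GCAU" * 10)


@pytest.fixture(scope="session")
def ideal60():
    return build_ideal_duplex("GCAUGC" * 10)


@pytest.fixture(scope="session")
def cag20():
    return build_repeat_construct("20xCAG")


@pytest.fixture(scope="session")
def cag20_pm(cag20):
    return infer_pairing(cag20)
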