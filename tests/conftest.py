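import pytest

from totorisk import ConcentrationRecord, ExposureModel, default_element_table


@pytest.fixture(scope="session")
def element_table():
    return default_element_table()


@pytest.fixture(scope="session")
def exposure():
    """The published study's exposure settings (all package defaults)."""
    return ExposureModel()


def make_record(element="Zn", value=17.2, censored=False, tissue="muscle",
                habitat="estuarine", season="winter", group="MF", fish_id="F001"):
    return ConcentrationRecord(
        fish_id=fish_id, tissue=tissue, habitat=habitat, season=season,
        group=group, element=element,
        value=None if censored else value, censored=censored,
    )


@pytest.fixture
def small_records():
    """A handful of muscle Zn records plus censored Pb, spread over two strata."""
    recs = [
        make_record(value=v, fish_id=f"F{i:03d}")
        for i, v in enumerate([1.0, 2.0, 4.0, 8.0])
    ]
    recs += [
        make_record(element="Pb", censored=True, fish_id=f"F{i:03d}", season="autumn",
                    habitat="rocky", group="UN")
        for i in range(10, 20)
    ]
    return recs
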