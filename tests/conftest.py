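from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

import plateqc as pq

DATA = Path(__file__).parent / "data"

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def p400():
    return pq.load_panel("p400")


@pytest.fixture(scope="session")
def toy_panel():
    return pq.load_panel(DATA / "toy_panel.csv")


@pytest.fixture(scope="session")
def toy_dataset(toy_panel):
    return pq.read_plate(DATA / "toy_plate.csv", toy_panel)


@pytest.fixture(scope="session")
def toy_qc(toy_dataset):
    return pq.run_qc(toy_dataset)


@pytest.fixture(scope="session")
def mini_panel():
    return pq.make_panel({"amino acids": 4, "phosphatidylcholines": 4})
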