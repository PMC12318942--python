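import pytest

from psmcea import make_paper_fixture, run_base_case


@pytest.fixture(scope="session")
def all_rand_config():
    return make_paper_fixture("all_randomized")


@pytest.fixture(scope="session")
def cps5_config():
    return make_paper_fixture("cps_ge5")


@pytest.fixture(scope="session")
def base_all(all_rand_config):
    return run_base_case(all_rand_config)


@pytest.fixture(scope="session")
def base_cps5(cps5_config):
    return run_base_case(cps5_config)
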