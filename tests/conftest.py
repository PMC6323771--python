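import pytest

from gist_cua import default_life_table, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def base_results(params, life_table):
    """Deterministic lifetime results for all six options (shared run)."""
    from gist_cua import evaluate_options

    return evaluate_options(params, life_table)
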