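import pytest

from cazstarve.corpus import load_expression_fixture, load_proteome_fixture


@pytest.fixture(scope="session")
def expression_fixture():
    """(gene_records, expression_matrix) from the packaged printed table."""
    return load_expression_fixture()


@pytest.fixture(scope="session")
def gene_records(expression_fixture):
    return expression_fixture[0]


@pytest.fixture(scope="session")
def expression_matrix(expression_fixture):
    return expression_fixture[1]


@pytest.fixture(scope="session")
def proteome_table():
    return load_proteome_fixture()
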