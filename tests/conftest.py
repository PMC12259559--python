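import pytest

import maxlogit as ml


@pytest.fixture(scope="session")
def table2():
    return ml.load_fixture("table2_cohort")


@pytest.fixture(scope="session")
def table4():
    return ml.load_fixture("table4_panels")


@pytest.fixture(scope="session")
def table2_patients(table2):
    """Matrix restricted to the 32 patients, paired with shock/sepsis labels."""
    matrix = table2.matrix.subset_samples(table2.shock_vs_sepsis.sample_ids)
    return matrix, table2.shock_vs_sepsis


@pytest.fixture
def toy_matrix():
    return ml.ExpressionMatrix(
        gene_ids=("GENE1", "GENE2"),
        sample_ids=("s1", "s2", "s3"),
        values=[[1.0, 2.5, 3.25], [0.5, 0.0, 10.0]],
        scale="identity",
    )
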