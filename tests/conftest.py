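import numpy as np
import pytest

from specmod import (
    ExpressionMatrix,
    PlantedDesign,
    generate_annotation,
    generate_expression,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_design():
    """A reduced planted design for fast unit tests (4 x 40 genes)."""
    return PlantedDesign(
        m_per_module=(40, 40, 40, 40),
        n_samples=25,
        within_corr=0.8,
        n_terms_per_module=8,
        term_coverage=0.6,
        background_terms=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_planted(small_design):
    ge, labels = generate_expression(small_design)
    ann = generate_annotation(small_design, labels, ge.gene_ids)
    return ge, labels, ann


def random_expression(rng, m=10, n=6):
    return ExpressionMatrix(
        [f"g{i}" for i in range(m)], rng.normal(size=(m, n))
    )
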