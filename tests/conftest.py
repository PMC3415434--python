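import pytest

from sinetrace.construct import builtin_template, default_construct
from sinetrace.synthetic import GenomeParams, generate_cohort, generate_genome
from sinetrace.tprt import SlippageParams


@pytest.fixture(scope="session")
def a70():
    return builtin_template("A70D")


@pytest.fixture(scope="session")
def a30():
    return builtin_template("A30D")


@pytest.fixture(scope="session")
def construct():
    return default_construct("A70D")


@pytest.fixture(scope="session")
def genome():
    return generate_genome(GenomeParams(), seed=42)


@pytest.fixture(scope="session")
def cohort(genome, construct):
    """226-insert cohort at the default class mix and slippage model."""
    return generate_cohort(genome, construct, n=226, seed=1)


@pytest.fixture(scope="session")
def cohort_noslip(genome, construct):
    """500-insert cohort with slippage disabled: tails are exact template
    prefixes, so priming and per-segment truth are string-identifiable."""
    return generate_cohort(
        genome, construct, n=500, seed=3, slippage=SlippageParams(p_dissoc0=0.0)
    )
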