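"""Shared fixtures: one default synthetic study reused across the suite."""

import pytest

from lazpipe import differential, expression
from lazpipe.enrichment import load_ontology
from lazpipe.simulate import (
    DEFAULT_EXCLUDE_TERMS,
    DEFAULT_INCLUDE_TERMS,
    SimParams,
    generate_bundle,
)


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic study (2 tissues x 5 times x 3 reps)."""
    return generate_bundle(SimParams(seed=1))


@pytest.fixture(scope="session")
def summary(bundle):
    rpkm = expression.compute_rpkm(bundle.counts, bundle.lengths)
    return expression.summarize_conditions(rpkm, bundle.design)


@pytest.fixture(scope="session")
def diff(summary):
    return differential.compute_differential(summary)


@pytest.fixture(scope="session")
def dag(bundle):
    return load_ontology(bundle.obo_text)


@pytest.fixture(scope="session")
def selection(bundle, diff, dag):
    tf_flags = differential.select_tf_genes(
        bundle.annotations, dag, DEFAULT_INCLUDE_TERMS, DEFAULT_EXCLUDE_TERMS, diff.index
    )
    return differential.flag_selection(diff, tf_flags)
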