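"""Shared fixtures: one mid-sized synthetic genome carried through the pipeline."""

import pytest

from utrome import genome_model as gm
from utrome import panel_design as pdsg
from utrome import synthetic_fixtures as fx


@pytest.fixture(scope="session")
def fixture_genome():
    """~100-gene mini-genome with generator truth."""
    return fx.simulate_genome(n_genes=100, seed=7)


@pytest.fixture(scope="session")
def fixture_models(fixture_genome):
    models, failures = gm.read_annotation(
        fixture_genome.gtf_text(), fixture_genome.genome, from_string=True
    )
    assert not failures
    return models


@pytest.fixture(scope="session")
def fixture_loci(fixture_genome, fixture_models):
    loci, failures = gm.resolve_utr_loci(fixture_models, fixture_genome.genome)
    assert not failures
    return loci


@pytest.fixture(scope="session")
def fixture_panel(fixture_genome, fixture_loci):
    return pdsg.design_panel(fixture_loci, fixture_genome.genome)


@pytest.fixture(scope="session")
def fixture_truth(fixture_genome):
    return {t.gene_id: t for t in fixture_genome.truth}


@pytest.fixture(scope="session")
def fixture_inserts(fixture_loci):
    """Expected insert sequences keyed by gene, the clone-verification panel."""
    return {locus.gene_id: locus.insert_sequence for locus in fixture_loci}
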