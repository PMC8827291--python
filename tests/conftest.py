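import pytest

from mutline.simulate import default_fixture, nin_like_gene_fixture


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic world: 500 kb, 50 genes, WT + 6 mutant
    lines spanning all causal mutation classes, seed 0."""
    return default_fixture(seed=0)


@pytest.fixture(scope="session")
def nin_fixture():
    """(genome, gene, variant, domains) for the four-exon candidate-gene
    fixture with the planted 1-bp frameshift deletion at CDS 2189."""
    return nin_like_gene_fixture()
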