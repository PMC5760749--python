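import pytest

import strainpair as sp


@pytest.fixture(scope="session")
def paper_like_pair():
    """One paper-like simulated pair (two planted regions) shared by tests."""
    cfg = sp.default_paper_like_config(seed=1)
    genome_a, genome_b, truth = sp.simulate_pair(cfg)
    return genome_a, genome_b, truth


@pytest.fixture(scope="session")
def paper_like_map(paper_like_pair):
    genome_a, genome_b, _ = paper_like_pair
    return sp.build_ortholog_map(genome_a, genome_b)


@pytest.fixture(scope="session")
def backbone_only_pair():
    """A pair with no planted regions (pure conserved backbone)."""
    cfg = sp.SimulationConfig(seed=11, n_backbone_genes=60)
    genome_a, genome_b, truth = sp.simulate_pair(cfg)
    return genome_a, genome_b, truth


def make_genome(genome_id, sequence, genes=()):
    """Tiny hand-built genome helper for unit tests."""
    gs = []
    for i, spec in enumerate(genes):
        gs.append(sp.Gene(ordinal=i, **spec))
    return sp.Genome(genome_id=genome_id, sequence=sequence, genes=gs)
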