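import pytest

from phagectx import simulate as sim


@pytest.fixture(scope="session")
def cohort():
    """12 synthetic genomes in 3 clades with the conserved module planted."""
    spec = sim.SynthSpec(seed=11, n_genomes=12, n_clades=3)
    genomes, genes, truths = sim.generate_cohort(spec)
    return spec, genomes, genes, truths


@pytest.fixture()
def genes_by_genome(cohort):
    _, _, genes, _ = cohort
    by = {}
    for g in genes:
        by.setdefault(g.genome_id, []).append(g)
    for gl in by.values():
        gl.sort(key=lambda g: (g.start, g.gene_id))
    return by
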