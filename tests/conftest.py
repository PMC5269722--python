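import numpy as np
import pytest

from exburden import (
    BurdenEngine,
    CohortConfig,
    GeneModel,
    Genome,
    SyntheticSpec,
    generate_annotation,
    generate_genome,
)


def make_gene(gene_id, chrom, strand, exon_lists, biotype="lncRNA"):
    """Build a GeneModel from a list of per-transcript exon interval lists."""
    transcripts = [(f"{gene_id}.t{i + 1}", sorted(ex)) for i, ex in enumerate(exon_lists)]
    return GeneModel(gene_id=gene_id, gene_name=gene_id, chrom=chrom,
                     strand=strand, biotype=biotype, transcripts=transcripts)


@pytest.fixture
def toy_genome():
    """Tiny explicit genome for hand-checkable context arithmetic."""
    return Genome({"chrA": "ACGTA", "chrB": "ACNTA", "chrC": "ACGTACGTACGTACGT"})


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def synth_cohort(default_spec):
    """The standard synthetic study: 1 Mb genome, 50 genes, G=30.

    Genome and annotation are fixed across seeds; mutation catalogues and
    subsampling vary per run. The engine caches regions and profiles.
    """
    genome = generate_genome(default_spec)
    genes = generate_annotation(default_spec, genome)
    engine = BurdenEngine(genes, genome, CohortConfig())
    return default_spec, genome, genes, engine


@pytest.fixture(scope="session")
def small_genome_spec():
    """100 kb single-chromosome spec used for randomizer audits."""
    return SyntheticSpec(n_chroms=1, chrom_length=100_000, n_genes=5, seed=3)
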