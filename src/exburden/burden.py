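"""Gene-level mutation burden testing.

For each gene, exonic mutation events are compared with events in a
trinucleotide-matched subsample of its background using a one-sided
hypergeometric (upper-tail) test on position-genomes: every genomic position
is counted once per sequenced genome, so the exonic population size is
N = eligible exonic length x G and the background population size is
n = |sampled background positions| x G. Genes below the minimum exonic or
background mutation-count filter are excluded before Benjamini-Hochberg FDR
correction, which is applied once per gene stratum.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel, build_background, build_genome_exon_mask
from .genome import Genome
from .mutations import MutationCatalogue, collapse_recurrent, map_mutations
from .trinuc import positions_by_trinuc, subsample_background, trinucleotide_profile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyInputs:
    """The four contingency cells for one gene, in position-genome units.

    M mutated exonic position-genomes out of N; m mutated background
    position-genomes out of n. (N - M and n - m are the unmutated cells.)
    """

    M: int
    N: int
    m: int
    n: int

    def __post_init__(self):
        if not (0 <= self.M <= self.N) or not (0 <= self.m <= self.n):
            raise ValueError("contingency cells must satisfy 0 <= M <= N and 0 <= m <= n")
        if self.N <= 0 or self.n <= 0:
            raise ValueError("population sizes N and n must be positive")


@dataclass
class GeneResult:
    """One output row: counts, position-genome lengths, p/Q and per-kb rates."""

    gene_id: str
    gene_name: str
    M: int
    N: int
    m: int
    n: int
    pval: float
    qval: float = math.nan
    stratum: str = "all"

    @property
    def ex_rate(self) -> float:
        """Exonic mutation rate, mutations per kb of position-genomes."""
        return 1000.0 * self.M / self.N

    @property
    def bg_rate(self) -> float:
        return 1000.0 * self.m / self.n

    @property
    def ratio(self) -> float:
        """Exonic / background rate ratio; NaN (reported NA) when m = 0."""
        if self.m == 0:
            return math.nan
        return self.ex_rate / self.bg_rate


def hypergeometric_enrichment(ci: ContingencyInputs) -> float:
    """Upper-tail hypergeometric p-value for exonic mutation enrichment.

    P(X >= M) where X ~ Hypergeom(population N + n, successes M + m,
    draws N): the probability that, were the M + m mutated position-genomes
    scattered at random over the combined exon + background population, at
    least the observed number would land in the exonic draw. Inclusive of
    the observed count; M + m = 0 returns 1 by convention.
    """
    if ci.M + ci.m == 0:
        return 1.0
    return float(hypergeom.sf(ci.M - 1, ci.N + ci.n, ci.M + ci.m, ci.N))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Q), input order kept."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def per_gene_seed(master_seed: int, gene_id: str) -> int:
    """Deterministic per-gene seed independent of gene order or scheduling."""
    h = hashlib.blake2b(f"{master_seed}:{gene_id}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2**31)


@dataclass
class CohortConfig:
    """Tunable parameters of a cohort run.

    window: background extension in bp on each side of the gene body.
    min_exonic_mut / min_background_mut: genes with fewer mutation events are
    excluded before FDR correction.
    q_report_threshold: Q cutoff used when flagging candidates (0.1 strict,
    0.2 relaxed).
    """

    window: int = 10_000
    min_exonic_mut: int = 1
    min_background_mut: int = 1
    seed: int = 0
    q_report_threshold: float = 0.1
    n_cores: int = 1


class BurdenEngine:
    """Precomputes per-gene regions and trinucleotide profiles for a fixed
    (annotation, genome) pair so that multiple catalogues or seeds can be
    analysed without repeating interval arithmetic and sequence scans."""

    def __init__(
        self,
        genes: list[GeneModel],
        genome: Genome,
        config: CohortConfig | None = None,
        mask_genes: list[GeneModel] | None = None,
    ):
        self.config = config or CohortConfig()
        self.genome = genome
        self.genes = sorted(genes, key=lambda g: g.gene_id)
        mask_source = mask_genes if mask_genes is not None else genes
        mask = build_genome_exon_mask(mask_source)
        self._prepared = []
        for gene in self.genes:
            if gene.chrom not in genome:
                logger.warning("gene %s: chromosome %s absent from genome; skipped",
                               gene.gene_id, gene.chrom)
                continue
            regions = build_background(
                gene,
                mask.get(gene.chrom, np.empty((0, 2), dtype=np.int64)),
                chrom_length=genome.length(gene.chrom),
                window=self.config.window,
            )
            ex_prof, _ = trinucleotide_profile(genome, gene.chrom, regions.exonic)
            if ex_prof.eligible_len == 0:
                logger.warning("gene %s has no eligible exonic positions; skipped",
                               gene.gene_id)
                continue
            _, bg_pos = trinucleotide_profile(genome, gene.chrom, regions.background)
            bg_by_t = positions_by_trinuc(genome, gene.chrom, bg_pos)
            self._prepared.append((gene, regions, ex_prof, bg_by_t))

    def run(
        self,
        cat: MutationCatalogue,
        seed: int | None = None,
        strata: dict[str, str] | None = None,
    ) -> list[GeneResult]:
        """Analyse one mutation catalogue.

        Recurrent mutations are collapsed, each gene's background is
        subsampled with a seed derived deterministically from the master seed
        and its gene_id, events are mapped, filtered genes are dropped, and
        Benjamini-Hochberg correction is applied independently within each
        stratum. Results are sorted by (qval, pval).
        """
        cfg = self.config
        master_seed = cfg.seed if seed is None else seed
        G = cat.n_genomes
        collapsed = collapse_recurrent(cat)

        results: list[GeneResult] = []
        n_filtered = 0
        for gene, regions, ex_prof, bg_by_t in self._prepared:
            sampled = subsample_background(
                ex_prof, bg_by_t, per_gene_seed(master_seed, gene.gene_id)
            )
            M, m = map_mutations(regions, collapsed, sampled.positions)
            if M < cfg.min_exonic_mut or m < cfg.min_background_mut:
                n_filtered += 1
                continue
            N = ex_prof.eligible_len * G
            n = len(sampled.positions) * G
            if n == 0:
                n_filtered += 1
                continue
            ci = ContingencyInputs(M=M, N=N, m=m, n=n)
            stratum = (strata or {}).get(gene.gene_id, "all")
            results.append(GeneResult(gene_id=gene.gene_id, gene_name=gene.gene_name,
                                      M=M, N=N, m=m, n=n,
                                      pval=hypergeometric_enrichment(ci),
                                      stratum=stratum))
        logger.info("tested %d genes (%d excluded by the mutation-count filter)",
                    len(results), n_filtered)
        if not results:
            logger.warning("no genes passed the mutation-count filters")
            return []

        for label in sorted({r.stratum for r in results}):
            group = [r for r in results if r.stratum == label]
            qvals = bh_adjust([r.pval for r in group])
            for r, q in zip(group, qvals):
                r.qval = float(q)
        results.sort(key=lambda r: (r.qval, r.pval, r.gene_id))
        return results


def run_cohort(
    genes: list[GeneModel],
    genome: Genome,
    cat: MutationCatalogue,
    config: CohortConfig | None = None,
    mask_genes: list[GeneModel] | None = None,
    strata: dict[str, str] | None = None,
) -> list[GeneResult]:
    """One-shot cohort analysis; see BurdenEngine for the reusable form."""
    return BurdenEngine(genes, genome, config, mask_genes=mask_genes).run(cat, strata=strata)
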