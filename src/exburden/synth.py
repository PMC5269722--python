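"""Self-contained synthetic fixtures: genome, annotation and signature-driven
mutation catalogues.

The generator emulates the statistical structure the burden test assumes:
context-dependent somatic mutation rates (a 64-context x 3-alt substitution
signature), multi-transcript gene models with introns, and optional "planted
driver" genes whose exonic mutation intensity is multiplied by a factor
theta — the alternative hypothesis the test targets, with the background
left untouched. Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneModel, project_exons
from .genome import BASES, Genome, N_TRINUC, decode_seq
from .mutations import MutationCatalogue, MutationRecord


def flat_signature() -> np.ndarray:
    """Uniform substitution signature: every (context, alt != centre) equal."""
    sig = np.ones((N_TRINUC, 4))
    for code in range(N_TRINUC):
        sig[code, (code >> 2) & 3] = 0.0  # alt == reference base is not a substitution
    return sig / sig.sum()


def cpg_skewed_signature(boost: float = 20.0) -> np.ndarray:
    """CpG-deamination-like signature: C>T in NCG contexts boosted.

    Exercises the reason the trinucleotide-matched subsampler exists — a
    composition-naive background would mistake CpG-rich exons for enriched.
    """
    sig = flat_signature() * 1.0
    t_idx = BASES.index("T")
    c_idx = BASES.index("C")
    g_idx = BASES.index("G")
    for left in range(4):
        code = 16 * left + 4 * c_idx + g_idx  # context N-C-G
        sig[code, t_idx] *= boost
    return sig / sig.sum()


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults describe a compact test cohort: a 1 Mb genome in two
    chromosomes at human-like GC content, 50 spliced multi-exon genes, and
    30 tumour genomes. The default per-genome rate of 2.2e-4 substitutions
    per bp gives a cohort-level density of ~6.6e-3 events per bp (rate x G),
    the density of a large pooled pan-cancer whole-genome catalogue; at this
    density a ~1 kb exonic region accumulates several events per cohort, so
    the minimum-mutation gene filter excludes few genes. In much sparser
    cohorts that filter conditions strongly on having seen an exonic event
    and the surviving genes' p-values are no longer uniform under the null.
    ``driver_multiplier`` is the factor theta applied to the exonic mutation
    intensity of the genes listed in ``driver_gene_ids``.
    """

    n_chroms: int = 2
    chrom_length: int = 500_000
    gc_fraction: float = 0.41
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (100, 400)
    intron_length: tuple[int, int] = (500, 3000)
    intergenic_gap: tuple[int, int] = (2000, 8000)
    n_samples: int = 30
    rate_per_bp: float = 2.2e-4
    mutations_per_sample: int | None = None
    signature: np.ndarray = field(default_factory=flat_signature)
    driver_gene_ids: tuple[str, ...] = ()
    driver_multiplier: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.driver_multiplier < 1.0:
            raise ValueError("driver_multiplier must be >= 1")
        sig = np.asarray(self.signature, dtype=float)
        if sig.shape != (N_TRINUC, 4) or np.any(sig < 0):
            raise ValueError("signature must be a non-negative (64, 4) matrix")
        self.signature = sig / sig.sum()


def generate_genome(spec: SyntheticSpec, seed: int | None = None) -> Genome:
    """I.i.d. random genome at the requested GC fraction."""
    rng = np.random.default_rng([spec.seed if seed is None else seed, 0])
    gc = spec.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = {}
    for i in range(spec.n_chroms):
        enc = rng.choice(4, size=spec.chrom_length, p=p).astype(np.uint8)
        seqs[f"chr{i + 1}"] = decode_seq(enc)
    return Genome(seqs)


def generate_annotation(spec: SyntheticSpec, genome: Genome, seed: int | None = None) -> list[GeneModel]:
    """Place non-overlapping multi-exon gene models along the chromosomes.

    Genes are laid out round-robin across chromosomes with intergenic gaps
    drawn from the spec range. Each gene gets a full-length transcript; genes
    with >= 3 exons may get a second, exon-skipping isoform so the merged
    projection is exercised by real multi-transcript structure.
    """
    rng = np.random.default_rng([spec.seed if seed is None else seed, 1])
    chroms = genome.chroms
    cursors = {c: int(rng.integers(*spec.intergenic_gap)) + 1 for c in chroms}
    genes: list[GeneModel] = []
    ci = 0
    attempts_left = spec.n_genes * len(chroms) * 4
    while len(genes) < spec.n_genes:
        if attempts_left <= 0:
            raise ValueError("synthetic spec infeasible: genes do not fit in the genome")
        attempts_left -= 1
        chrom = chroms[ci % len(chroms)]
        ci += 1
        n_ex = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        ex_lens = rng.integers(spec.exon_length[0], spec.exon_length[1] + 1, size=n_ex)
        in_lens = rng.integers(spec.intron_length[0], spec.intron_length[1] + 1,
                               size=max(n_ex - 1, 0))
        span = int(ex_lens.sum() + in_lens.sum())
        start = cursors[chrom]
        if start + span > genome.length(chrom) - 1:
            continue  # chromosome full; try the next one
        exons = []
        pos = start
        for j in range(n_ex):
            exons.append((pos, pos + int(ex_lens[j])))
            pos += int(ex_lens[j]) + (int(in_lens[j]) if j < n_ex - 1 else 0)
        gid = f"SYNG{len(genes) + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts = [(f"{gid}.t1", exons)]
        if n_ex >= 3 and rng.random() < 0.5:
            skip = int(rng.integers(1, n_ex - 1))  # drop an internal exon
            transcripts.append((f"{gid}.t2", [e for j, e in enumerate(exons) if j != skip]))
        genes.append(GeneModel(gene_id=gid, gene_name=gid, chrom=chrom, strand=strand,
                               biotype="lncRNA", transcripts=transcripts))
        cursors[chrom] = exons[-1][1] + int(rng.integers(*spec.intergenic_gap))
    return genes


def write_gtf(genes: list[GeneModel], path) -> None:
    """Emit gene/transcript/exon GTF records (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.span
            attrs = (f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                     f'gene_type "{g.biotype}";')
            fh.write(f"{g.chrom}\tsynth\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            for tid, exons in g.transcripts:
                ts, te = exons[0][0], exons[-1][1]
                tattrs = attrs + f' transcript_id "{tid}";'
                fh.write(f"{g.chrom}\tsynth\ttranscript\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t{tattrs}\n")
                for (xs, xe) in exons:
                    fh.write(f"{g.chrom}\tsynth\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t{tattrs}\n")


def _position_intensity(
    spec: SyntheticSpec, genome: Genome, genes: list[GeneModel]
) -> dict[str, np.ndarray]:
    """Per-position mutation intensity per genome, normalized so the
    genome-wide mean over eligible positions equals rate_per_bp at theta=1."""
    ctx_weight = spec.signature.sum(axis=1)  # marginal context weight
    weights = {}
    total = 0.0
    n_eligible = 0
    for chrom in genome.chroms:
        codes = genome.codes(chrom)
        w = np.where(codes >= 0, ctx_weight[np.clip(codes, 0, None)], 0.0)
        weights[chrom] = w
        total += w.sum()
        n_eligible += int((codes >= 0).sum())
    mean_w = total / n_eligible
    driver = set(spec.driver_gene_ids)
    for g in genes:
        if g.gene_id in driver:
            for s, e in project_exons(g):
                weights[g.chrom][s:e] *= spec.driver_multiplier
    return {c: spec.rate_per_bp * w / mean_w for c, w in weights.items()}


def simulate_mutations(
    spec: SyntheticSpec,
    genome: Genome,
    genes: list[GeneModel],
    seed: int | None = None,
) -> MutationCatalogue:
    """Draw per-sample somatic substitution catalogues from the signature.

    Each position's intensity is proportional to the signature weight of its
    trinucleotide context, multiplied by theta inside planted drivers' merged
    exons; the alt allele is drawn from the signature's conditional alt
    distribution for that context, so ref/alt are consistent with the genome.
    """
    rng = np.random.default_rng([spec.seed if seed is None else seed, 2])
    lam = _position_intensity(spec, genome, genes)
    chroms = genome.chroms
    lam_sums = np.array([lam[c].sum() for c in chroms])
    probs = {c: lam[c] / lam[c].sum() for c in chroms}
    chrom_p = lam_sums / lam_sums.sum()

    records: list[MutationRecord] = []
    for s in range(spec.n_samples):
        sample = f"S{s + 1:03d}"
        if spec.mutations_per_sample is not None:
            n_mut = spec.mutations_per_sample
        else:
            n_mut = int(rng.poisson(lam_sums.sum()))
        n_per_chrom = rng.multinomial(n_mut, chrom_p)
        for c, n_c in zip(chroms, n_per_chrom):
            if n_c == 0:
                continue
            pos = rng.choice(genome.length(c), size=n_c, replace=True, p=probs[c])
            codes = genome.codes(c)
            enc = genome.encoded(c)
            for p in sorted(int(x) for x in pos):
                code = int(codes[p])
                alt_w = spec.signature[code].copy()
                alt_w_sum = alt_w.sum()
                alt = int(rng.choice(4, p=alt_w / alt_w_sum))
                records.append(MutationRecord(chrom=c, start=p, end=p + 1,
                                              ref=BASES[enc[p]], alt=BASES[alt],
                                              sample_id=sample, mtype="substitution"))
    return MutationCatalogue(records=records, n_genomes=spec.n_samples)


def generate_fixture(
    spec: SyntheticSpec, mutation_seed: int | None = None
) -> tuple[Genome, list[GeneModel], MutationCatalogue]:
    """Genome + annotation + catalogue in one call (shared spec seed)."""
    genome = generate_genome(spec)
    genes = generate_annotation(spec, genome)
    cat = simulate_mutations(spec, genome, genes, seed=mutation_seed)
    return genome, genes, cat
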