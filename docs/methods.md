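# Methods

## Model and procedure

For each tested gene the pipeline executes five steps.

1. **Region definition.** All exons of all transcripts are merged into one
   exonic projection (abutting intervals coalesce — interval counts change,
   lengths and statistics do not). The background is the gene body extended
   by a `window` of 10,000 bp on each side, clipped to the chromosome,
   minus the gene's own exons and minus the union of merged exons of every
   gene in the genome-wide annotation. The mask includes the tested genes
   themselves: "another gene" is any record with a different `gene_id`, so
   one tested gene's exon can never inflate another's background.
2. **Trinucleotide profiling.** Every position is assigned the
   reference-strand trinucleotide at `[p-1, p+2)`; the context may extend
   past an interval edge into adjacent genomic sequence. Positions whose
   context leaves the chromosome or contains a non-ACGT base are
   ineligible and drop out of profiles, position lists and the population
   sizes. Profiles use all 64 reference-strand trinucleotides without
   reverse-complement collapsing: the subsampler balances sequence
   composition, for which strand symmetry is unnecessary; the 96-channel
   signature matrix is the motivation, not the data structure.
3. **Composition-matched subsampling.** With exonic context counts c_t and
   background pools of size b_t, the number of complete rounds is
   k = min over {t : c_t > 0} of floor(b_t / c_t); for each such t, k·c_t
   positions are drawn uniformly without replacement. A partial final
   round is never drawn, so the sampled composition equals k x the exonic
   composition *exactly*, every run — the property the whole design rests
   on. If some exonic context is absent from the background, k = 0 and the
   gene later fails the background-mutation filter. One subsample is drawn
   per gene per run; variability across draws is surfaced through the seed
   rather than averaged away.
4. **Mutation mapping.** Catalogues retain only substitutions and 1-nt
   indels; records matching a germline blacklist on (chrom, pos, ref, alt)
   are removed; identical changes recurring across samples collapse to one
   event while distinct changes at one position stay separate. An event is
   localized by its BED start (insertions anchor to the base left of the
   insertion point). M counts events inside the exonic projection, m counts
   events on sampled background positions; events elsewhere — including
   un-sampled background — count nowhere.
5. **Test and FDR.** Position-genomes: N = eligible exonic length x G,
   n = |sampled positions| x G, with G the cohort genome count supplied as
   metadata (samples with no retained mutations still contribute trials).
   The p-value is the inclusive hypergeometric upper tail
   P(X >= M), X ~ HG(N+n, M+m, N), computed with a numerically stable
   survival function; M + m = 0 returns 1 by convention. Genes with
   M < 1 or m < 1 (configurable) are excluded *before* correction and do
   not enter the Benjamini-Hochberg denominator. BH runs independently
   within each gene stratum (e.g. literature-curated cancer genes vs the
   rest), supporting stratified FDR; results sort by (Q, p).

Annotation handling: GTF is read as 1-based inclusive and converted to the
internal 0-based half-open convention (BED is read natively half-open). The
intergenic filter removes genes with a transcript overlapping a
protein-coding gene on the opposite strand, or with a gene body overlapping
or within 10 kb (closest points of the merged gene spans) of a same-strand
protein-coding gene; a whitelist is re-added afterwards and passes through
the same background mask as every other gene. Coding-potential screening is
accepted as a precomputed exclusion list of gene ids rather than
reimplementing a classifier.

## Randomizers

Neutral catalogues are built by reassigning each mutation to a uniformly
chosen position with the identical reference trinucleotide, either within
its fixed genome-aligned 50 kb partition (partitions start at 0 on every
chromosome) or within a 50 kb window centred on the mutation and clipped to
the chromosome. For 1-nt indels the matched k-mer is the centred
trinucleotide — a declared convention, since "surrounding nucleotides" is
underdetermined. The origin is always an allowed destination; excluding it
would force context-rare mutations to move and bias the spectrum. Ref/alt
travel with the record, so both schemes conserve the total count,
per-sample counts, and the joint (context, alt) substitution spectrum as
exact multisets. Recurrent collapse is applied after randomization when the
null catalogue is analysed, mirroring the real-data order.

## Synthetic cohorts

The generator emulates what the test assumes about real data: i.i.d.
genome sequence at a chosen GC fraction (default 0.41, human-like);
non-overlapping spliced gene models (default 50 genes across a 1 Mb,
two-chromosome genome; 2–5 exons of 100–400 bp separated by 0.5–3 kb
introns, 2–8 kb intergenic gaps, occasional exon-skipping second isoforms);
and per-sample catalogues drawn position-by-position with intensity
proportional to a 64-context substitution signature (flat default, plus a
CpG C>T-skewed preset that exercises the subsampler's reason for existing),
with the alt allele drawn from the signature's conditional distribution.
Planted drivers multiply the intensity on their merged exons by a factor
theta (default 20), leaving the background untouched — exactly the
alternative hypothesis the statistic targets.

Default density is 2.2e-4 substitutions per bp per genome with G = 30,
i.e. a cohort-level density of ~6.6e-3 events per bp — the regime of a
large pooled pan-cancer whole-genome catalogue, where a ~1 kb exonic
region expects several events per cohort. This matters beyond realism: the
minimum-mutation gene filter is *selective* in sparse cohorts. If the
expected exonic count per gene is well below 1, conditioning on "at least
one exonic event" enriches the surviving genes for upward fluctuations and
their p-values are no longer uniform under the null; at the default
density the filter excludes almost nothing and the discrete statistic
shows its expected conservative (deflated) p-value distribution. Power
checks use a planted theta = 20 driver sized to expect ~10 exonic events
per cohort — just above the 8-event regime where recovery should still be
near-certain — which is the hardest case worth asserting; at the default
density the driver expects ~180 events and detection is trivial.

What the generator does **not** emulate: replication-timing and
expression-linked rate covariates, chromatin-state heterogeneity, repeat
structure, sequencing artefacts, or signatures beyond trinucleotide
context. Passing tests therefore demonstrate correctness of the algorithm
under its own model assumptions, not robustness to every confounder of
real tumour genomes.

## Numerical and design choices

* P-values go through `scipy.stats.hypergeom.sf(M-1, N+n, M+m, N)`
  (log-space stable); tests verify it against exhaustive enumeration over
  all position assignments for every instance with N + n <= 12 at 1e-12
  relative error.
* BH adjustment delegates to `statsmodels` with hand-computed step-up
  examples frozen in tests; input order is preserved.
* Determinism: every run is reproducible bit-for-bit given inputs and a
  master seed. Per-gene subsampling seeds derive from
  blake2b(master_seed, gene_id), so results are independent of gene order
  and of any parallel scheduling; the `n_cores` option cannot change
  output.
* Rate columns report events per kb of position-genomes; the
  exonic/background ratio is reported as NA when m = 0 (the p-value is
  still computed).
* A substitution whose stated ref disagrees with the genome is kept with a
  warning — catalogues and FASTA builds may disagree, and the statistic
  uses only position.
* Degenerate inputs: genes with no exons, no eligible exonic positions, or
  an unsatisfiable background composition are dropped with warnings rather
  than failing the cohort; an empty catalogue yields an empty result table.

## Known limitations

* Burden-only: no functional-impact weighting, clustering statistic, or
  covariate-regression background; a gene must carry raw excess burden to
  score.
* The mutation-count filter's selection effect (above) makes the test
  anti-conservative in very sparse cohorts; users analysing small cohorts
  should raise the minimum-count thresholds or interpret Q-values
  cautiously.
* Counting collapsed events while distinct changes at one position remain
  separate means M can exceed the number of distinct mutated positions —
  accepted as the method's own convention.
* Hypermutated-sample removal (`filter_hypermutators`) and region masking
  (`filter_masked_regions`, e.g. for repeat annotations) exist as optional
  catalogue pre-filters but default off: both discard genuine signal along
  with noise, and burden testing tends to lose more than it gains from
  them.
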