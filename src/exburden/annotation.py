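"""Gene annotation parsing, exon projection, intergenic filtering and
background-region construction.

Internal coordinates are 0-based half-open throughout; GTF input is read as
1-based inclusive (GENCODE dialect), BED input as 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .intervals import (
    as_intervals,
    clip_intervals,
    merge_intervals,
    subtract_intervals,
    total_length,
)

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


@dataclass
class GeneModel:
    """A gene with its transcripts' exon intervals.

    Exon intervals are 0-based half-open; all exons of a gene share one
    chromosome. Transcript grouping is retained only to attribute exons —
    region construction uses the merged projection across transcripts.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    biotype: str
    transcripts: list[tuple[str, list[tuple[int, int]]]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        """Gene body: min exon start to max exon end across transcripts."""
        starts = [s for _, exons in self.transcripts for s, _ in exons]
        ends = [e for _, exons in self.transcripts for _, e in exons]
        return min(starts), max(ends)

    def all_exons(self) -> list[tuple[int, int]]:
        return [iv for _, exons in self.transcripts for iv in exons]


@dataclass
class RegionSet:
    """Per-gene merged exonic intervals and background intervals.

    ``background`` is the gene body plus flanking windows, minus the gene's
    own exonic projection and minus every merged exon in the genome-wide
    annotation. The two interval lists are mutually disjoint by construction.
    """

    gene_id: str
    chrom: str
    exonic: np.ndarray
    background: np.ndarray

    @property
    def exonic_len_bp(self) -> int:
        return total_length(self.exonic)

    @property
    def background_len_bp(self) -> int:
        return total_length(self.background)


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gene_annotation(gtf_stream) -> list[GeneModel]:
    """Parse gene models from a GTF text stream (GENCODE dialect).

    Only ``gene`` and ``exon`` features are used; ``gene`` lines supply
    name/biotype metadata, exons build the transcript structure. Exons
    lacking a transcript_id are attached to a synthetic single transcript.
    Genes with zero exons are dropped with a warning.

    Parameters
    ----------
    gtf_stream : iterable of str or path-like
        Open text stream or a filesystem path.
    """
    if isinstance(gtf_stream, (str, bytes)) or hasattr(gtf_stream, "__fspath__"):
        with open(gtf_stream) as fh:
            return parse_gene_annotation(fh)

    meta: dict[str, dict] = {}
    exons: dict[str, dict[str, list[tuple[int, int]]]] = {}
    order: list[str] = []

    for lineno, line in enumerate(gtf_stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(f"malformed GTF line {lineno}: expected 9 tab-separated fields")
        chrom, _, feature, start_s, end_s, _, strand, _, attrs_s = fields
        if feature not in ("gene", "exon"):
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(f"malformed GTF line {lineno}: non-numeric coordinates") from None
        attrs = _parse_attributes(attrs_s)
        gid = attrs.get("gene_id")
        if gid is None:
            raise GtfParseError(f"malformed GTF line {lineno}: missing gene_id attribute")
        start0, end0 = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        if gid not in meta:
            meta[gid] = {"chrom": chrom, "strand": strand,
                         "name": attrs.get("gene_name", gid),
                         "biotype": attrs.get("gene_type", attrs.get("gene_biotype", ""))}
            order.append(gid)
        if feature == "gene":
            meta[gid].update(name=attrs.get("gene_name", meta[gid]["name"]),
                             biotype=attrs.get("gene_type", attrs.get("gene_biotype", meta[gid]["biotype"])))
            continue
        if end0 <= start0:
            logger.warning("line %d: exon with end <= start rejected (gene %s)", lineno, gid)
            continue
        tid = attrs.get("transcript_id") or f"{gid}.synthetic_tx"
        exons.setdefault(gid, {}).setdefault(tid, []).append((start0, end0))

    genes: list[GeneModel] = []
    for gid in order:
        m = meta[gid]
        if gid not in exons:
            logger.warning("gene %s has no exon records; dropped", gid)
            continue
        transcripts = [(tid, sorted(ivs)) for tid, ivs in exons[gid].items()]
        genes.append(GeneModel(gene_id=gid, gene_name=m["name"], chrom=m["chrom"],
                               strand=m["strand"], biotype=m["biotype"],
                               transcripts=transcripts))
    return genes


def project_exons(gene: GeneModel) -> np.ndarray:
    """Merged exonic projection: union of all exons across all transcripts.

    Returns the minimal sorted disjoint interval set; abutting intervals are
    coalesced (affects interval counts, never lengths).
    """
    return merge_intervals(gene.all_exons())


def _span_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap in bp between two half-open spans; 0 if they overlap or abut."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return max(a[0] - b[1], b[0] - a[1], 0)


def filter_intergenic(
    lnc_genes: list[GeneModel],
    pc_genes: list[GeneModel],
    same_strand_distance: int = 10_000,
    whitelist: set[str] | frozenset[str] = frozenset(),
) -> list[GeneModel]:
    """Keep only intergenic genes: no transcript overlapping a protein-coding
    gene on the opposite strand, and neither overlapping nor within
    ``same_strand_distance`` bp (at the closest point of the gene bodies) of
    one on the same strand. Whitelisted gene_ids are re-added after filtering
    regardless of the rules.
    """
    pc_by_chrom: dict[str, list[GeneModel]] = {}
    for g in pc_genes:
        pc_by_chrom.setdefault(g.chrom, []).append(g)
    known_chroms = set(pc_by_chrom) | {g.chrom for g in pc_genes}

    kept: list[GeneModel] = []
    for lnc in lnc_genes:
        if lnc.chrom not in known_chroms and pc_genes:
            logger.warning("gene %s on chromosome %s absent from protein-coding "
                           "annotation; retained", lnc.gene_id, lnc.chrom)
            kept.append(lnc)
            continue
        violates = False
        span = lnc.span
        for pc in pc_by_chrom.get(lnc.chrom, []):
            pc_span = pc.span
            if pc.strand != lnc.strand:
                # any transcript overlapping the pc gene body
                for _, exons in lnc.transcripts:
                    t_span = (min(s for s, _ in exons), max(e for _, e in exons))
                    if _span_distance(t_span, pc_span) == 0 and t_span[0] < pc_span[1] and pc_span[0] < t_span[1]:
                        violates = True
                        break
            else:
                if _span_distance(span, pc_span) <= same_strand_distance:
                    violates = True
            if violates:
                break
        if not violates:
            kept.append(lnc)

    kept_ids = {g.gene_id for g in kept}
    for lnc in lnc_genes:
        if lnc.gene_id in whitelist and lnc.gene_id not in kept_ids:
            kept.append(lnc)
            kept_ids.add(lnc.gene_id)
    return kept


def build_genome_exon_mask(genes: list[GeneModel]) -> dict[str, np.ndarray]:
    """Union of merged exons of all genes, per chromosome."""
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).extend(g.all_exons())
    return {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}


def build_background(
    gene: GeneModel,
    genome_exon_mask: np.ndarray | list,
    chrom_length: int,
    window: int = 10_000,
) -> RegionSet:
    """Construct a gene's exonic and background regions.

    Background = gene body extended by ``window`` bp on each side (clipped to
    the chromosome), minus the gene's own merged exons, minus every exon in
    the genome-wide mask (which includes the tested genes themselves, so one
    tested gene's exon can never sit in another's background).
    """
    if window < 0:
        raise ValueError("background window must be non-negative")
    exonic = project_exons(gene)
    start, end = gene.span
    flank = clip_intervals([(start - window, end + window)], 0, chrom_length)
    background = subtract_intervals(flank, exonic)
    mask = as_intervals(genome_exon_mask)
    if len(mask):
        background = subtract_intervals(background, mask)
    return RegionSet(gene_id=gene.gene_id, chrom=gene.chrom,
                     exonic=exonic, background=background)


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column whitespace-separated chromosome length table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"chromosome sizes line {lineno}: expected name and length")
            sizes[parts[0]] = int(parts[1])
    return sizes


def read_gene_list(path) -> set[str]:
    """One gene_id per line (exclusion or whitelist files)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
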