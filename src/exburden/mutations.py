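"""Somatic mutation catalogues: BED parsing, germline filtering, recurrent
collapse, and mapping onto exonic / sampled-background regions.

Only single-nucleotide substitutions and length-1 indels are retained; every
event is localized by its BED start position (insertions are anchored to the
base to the left of the insertion point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .intervals import contains_positions

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


class BedParseError(ValueError):
    """Raised for malformed BED input; message names the offending line."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic substitution or length-1 indel in one sample."""

    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    sample_id: str
    mtype: str  # substitution | insertion1 | deletion1

    @property
    def key(self) -> tuple:
        """Identity for recurrent collapse: position and nucleotide change."""
        return (self.chrom, self.start, self.ref, self.alt)


@dataclass
class MutationCatalogue:
    """A cohort's somatic mutations plus the number of genomes they came from.

    ``n_genomes`` is supplied by the caller (cohort metadata), not inferred:
    samples with zero retained mutations still contribute sequenced positions.
    """

    records: list[MutationRecord] = field(default_factory=list)
    n_genomes: int = 1

    def __post_init__(self):
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")

    def __len__(self) -> int:
        return len(self.records)


def _classify(ref: str, alt: str) -> str | None:
    ref, alt = ref.upper(), alt.upper()
    if ref in _ACGT and alt in _ACGT and ref != alt:
        return "substitution"
    if ref == "-" and alt in _ACGT:
        return "insertion1"
    if ref in _ACGT and alt == "-":
        return "deletion1"
    return None


def parse_mutations(
    bed_stream,
    n_genomes: int,
    ref_col: int = 3,
    alt_col: int = 4,
    sample_col: int = 5,
) -> MutationCatalogue:
    """Read a mutation catalogue from BED text (0-based half-open).

    Records that are not single-nucleotide substitutions or length-1 indels
    are dropped and counted. Column indices for ref/alt/sample are 0-based
    and configurable to accommodate catalogue dialects.
    """
    if isinstance(bed_stream, (str, bytes)) or hasattr(bed_stream, "__fspath__"):
        with open(bed_stream) as fh:
            return parse_mutations(fh, n_genomes, ref_col, alt_col, sample_col)

    records: list[MutationRecord] = []
    dropped = 0
    n_lines = 0
    for lineno, line in enumerate(bed_stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        n_lines += 1
        fields = line.split("\t")
        needed = max(2, ref_col, alt_col, sample_col) + 1
        if len(fields) < needed:
            raise BedParseError(f"malformed BED line {lineno}: expected >= {needed} fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise BedParseError(f"malformed BED line {lineno}: non-numeric coordinates") from None
        ref, alt = fields[ref_col].upper(), fields[alt_col].upper()
        mtype = _classify(ref, alt)
        if mtype is None or (mtype == "substitution" and end - start != 1) \
                or (mtype == "deletion1" and end - start != 1):
            dropped += 1
            continue
        records.append(MutationRecord(chrom=fields[0], start=start, end=end,
                                      ref=ref, alt=alt,
                                      sample_id=fields[sample_col], mtype=mtype))
    if dropped:
        logger.info("dropped %d records that are not substitutions or 1-nt indels", dropped)
    if n_lines == 0:
        logger.warning("empty mutation file: catalogue has 0 records")
    return MutationCatalogue(records=records, n_genomes=n_genomes)


def write_mutations(cat: MutationCatalogue, path) -> None:
    """Serialize a catalogue back to the same BED dialect it is read from."""
    with open(path, "w") as fh:
        for r in cat.records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.ref}\t{r.alt}\t{r.sample_id}\n")


def filter_germline(
    cat: MutationCatalogue, blacklist: set[tuple[str, int, str, str]]
) -> MutationCatalogue:
    """Drop records exactly matching a germline-variant blacklist entry on
    (chrom, position, ref, alt); a different alt at the same position stays."""
    kept = [r for r in cat.records if (r.chrom, r.start, r.ref, r.alt) not in blacklist]
    removed = len(cat.records) - len(kept)
    if removed:
        logger.info("removed %d records matching the germline blacklist", removed)
    return replace(cat, records=kept)


def read_blacklist(path, ref_col: int = 3, alt_col: int = 4) -> set[tuple[str, int, str, str]]:
    """Load blacklist positions from the same BED column dialect as mutations."""
    out: set[tuple[str, int, str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.add((f[0], int(f[1]), f[ref_col].upper(), f[alt_col].upper()))
    return out


def filter_hypermutators(cat: MutationCatalogue, max_per_sample: int) -> MutationCatalogue:
    """Optional pre-filter: drop all records of samples carrying more than
    ``max_per_sample`` mutations. Off by default — hypermutators carry real
    signal too, and burden testing usually loses more than it gains here."""
    per_sample: dict[str, int] = {}
    for r in cat.records:
        per_sample[r.sample_id] = per_sample.get(r.sample_id, 0) + 1
    hyper = {s for s, c in per_sample.items() if c > max_per_sample}
    if hyper:
        logger.info("removed %d hypermutated samples (> %d mutations)",
                    len(hyper), max_per_sample)
    return replace(cat, records=[r for r in cat.records if r.sample_id not in hyper])


def filter_masked_regions(
    cat: MutationCatalogue, mask_by_chrom: dict[str, np.ndarray]
) -> MutationCatalogue:
    """Optional pre-filter: drop records inside masked intervals per
    chromosome (e.g. a repeat annotation). Off by default."""
    kept = []
    for r in cat.records:
        mask = mask_by_chrom.get(r.chrom)
        if mask is not None and len(mask) and bool(contains_positions(mask, [r.start])[0]):
            continue
        kept.append(r)
    removed = len(cat.records) - len(kept)
    if removed:
        logger.info("removed %d records in masked regions", removed)
    return replace(cat, records=kept)


def collapse_recurrent(cat: MutationCatalogue) -> MutationCatalogue:
    """Collapse identical mutations observed in several samples into one event.

    Identity is (chrom, start, ref, alt): the same nucleotide change at the
    same position counts once, while distinct changes at one position remain
    separate events. Idempotent; first-seen record representative is kept.
    """
    seen: dict[tuple, MutationRecord] = {}
    for r in cat.records:
        seen.setdefault(r.key, r)
    return replace(cat, records=list(seen.values()))


def map_mutations(
    regions, cat: MutationCatalogue, sampled_positions: np.ndarray | None = None
) -> tuple[int, int]:
    """Count collapsed mutation events in exons (M) and background (m).

    A record counts toward M if its start position lies inside the gene's
    merged exonic intervals, and toward m if it lies in ``sampled_positions``
    (the trinucleotide-matched background subsample). When no subsample is
    given, the full background intervals are used. Records elsewhere — or in
    un-sampled background positions — contribute to neither count.
    """
    starts = np.array([r.start for r in cat.records if r.chrom == regions.chrom],
                      dtype=np.int64)
    if starts.size == 0:
        return 0, 0
    M = int(contains_positions(regions.exonic, starts).sum())
    if sampled_positions is not None:
        sampled = np.asarray(sampled_positions, dtype=np.int64)
        m = int(np.isin(starts, sampled).sum())
    else:
        m = int(contains_positions(regions.background, starts).sum())
    return M, m
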