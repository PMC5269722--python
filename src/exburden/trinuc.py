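"""Trinucleotide profiling of genomic regions and composition-matched
background subsampling.

The subsampler is the heart of the background model: background positions are
drawn without replacement, in complete rounds, until the sampled set's
trinucleotide composition is exactly an integer multiple of the exonic
region's. This balances sequence composition between the exonic (foreground)
and background position sets so that context-dependent mutational signatures
cannot masquerade as exonic enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import N_TRINUC, Genome, TRINUCLEOTIDES


@dataclass
class TrinucleotideProfile:
    """Counts of the 64 reference-strand trinucleotides in a position set."""

    counts: np.ndarray  # shape (64,), non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_TRINUC,):
            raise ValueError("profile must have 64 trinucleotide counts")
        if np.any(self.counts < 0):
            raise ValueError("trinucleotide counts must be non-negative")

    @property
    def eligible_len(self) -> int:
        """Number of profiled positions (those with a valid ACGT context)."""
        return int(self.counts.sum())

    def as_dict(self) -> dict[str, int]:
        return {TRINUCLEOTIDES[i]: int(c) for i, c in enumerate(self.counts) if c}


@dataclass
class SampledBackground:
    """A trinucleotide-matched subsample of a gene's background positions.

    ``rounds`` is the number k of complete copies of the exonic profile that
    were drawn; the sampled profile equals exactly k x the exonic profile.
    """

    positions: np.ndarray  # sorted sampled background positions
    rounds: int
    profile: TrinucleotideProfile


def trinucleotide_profile(
    genome: Genome, chrom: str, intervals
) -> tuple[TrinucleotideProfile, np.ndarray]:
    """Profile the trinucleotide content of a set of disjoint intervals.

    Every position p inside the intervals is assigned the reference
    trinucleotide at [p-1, p+2); the context may extend beyond the interval
    boundary into adjacent genomic sequence. Positions whose context runs off
    the chromosome or contains a non-ACGT base are ineligible and excluded
    from both the profile and the returned position list.

    Returns
    -------
    (profile, eligible_positions)
    """
    codes = genome.codes(chrom)
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return TrinucleotideProfile(np.zeros(N_TRINUC, dtype=np.int64)), np.empty(0, dtype=np.int64)
    pos = np.concatenate([np.arange(s, e, dtype=np.int64) for s, e in iv])
    c = codes[pos]
    ok = c >= 0
    pos, c = pos[ok], c[ok]
    counts = np.bincount(c, minlength=N_TRINUC).astype(np.int64)
    return TrinucleotideProfile(counts), pos


def positions_by_trinuc(genome: Genome, chrom: str, positions) -> dict[int, np.ndarray]:
    """Group eligible positions by their trinucleotide context code."""
    pos = np.asarray(positions, dtype=np.int64)
    c = genome.codes(chrom)[pos]
    ok = c >= 0
    pos, c = pos[ok], c[ok]
    order = np.argsort(c, kind="stable")
    pos, c = pos[order], c[order]
    bounds = np.searchsorted(c, np.arange(N_TRINUC + 1))
    return {t: pos[bounds[t]:bounds[t + 1]] for t in range(N_TRINUC)
            if bounds[t + 1] > bounds[t]}


def subsample_background(
    exon_profile: TrinucleotideProfile,
    bg_positions_by_trinuc: dict[int, np.ndarray],
    seed: int | np.random.Generator,
) -> SampledBackground:
    """Draw background positions matching k complete copies of the exonic
    trinucleotide profile.

    Sampling proceeds without replacement; the number of complete rounds is
    k = min over trinucleotides t with exonic count c_t > 0 of
    floor(|background positions with context t| / c_t). For each such t,
    k*c_t positions are drawn uniformly without replacement. A partial final
    round is never drawn, so the sampled composition equals the exonic
    composition exactly (scaled by k). Deterministic given the seed.

    If some exonic trinucleotide is absent from the background, k = 0 and the
    sample is empty; the gene then fails the background-mutation filter
    downstream.
    """
    if exon_profile.eligible_len == 0:
        raise ValueError("exonic profile is empty; gene has no eligible exonic positions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    needed = np.flatnonzero(exon_profile.counts)
    k = min(
        (len(bg_positions_by_trinuc.get(int(t), ())) // int(exon_profile.counts[t])
         for t in needed),
        default=0,
    )
    if k == 0:
        empty = TrinucleotideProfile(np.zeros(N_TRINUC, dtype=np.int64))
        return SampledBackground(positions=np.empty(0, dtype=np.int64), rounds=0, profile=empty)

    chosen = []
    counts = np.zeros(N_TRINUC, dtype=np.int64)
    for t in needed:
        t = int(t)
        take = k * int(exon_profile.counts[t])
        pool = bg_positions_by_trinuc[t]
        chosen.append(rng.choice(pool, size=take, replace=False))
        counts[t] = take
    positions = np.sort(np.concatenate(chosen))
    return SampledBackground(positions=positions, rounds=int(k),
                             profile=TrinucleotideProfile(counts))
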