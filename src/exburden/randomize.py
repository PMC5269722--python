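"""Trinucleotide-context-preserving mutation randomization.

Two reassignment schemes build neutral null catalogues from a real one while
preserving each mutation's reference trinucleotide context (for 1-nt indels,
the context trinucleotide centred on the anchor position):

* fixed_window — the genome is divided into fixed, coordinate-aligned
  partitions (default 50 kb, starting at 0 on every chromosome) and each
  mutation moves to a uniformly chosen same-context position in its
  partition;
* sliding_window — a window of the same width is centred on each mutation
  and the destination is drawn from same-context positions inside it.

Both schemes preserve the total mutation count, per-sample counts and the
joint (trinucleotide, alt) substitution spectrum exactly; the origin position
is always an allowed destination (excluding it would bias context-rare
mutations toward forced movement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .genome import Genome
from .mutations import MutationCatalogue, MutationRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReassignmentScheme:
    mode: str  # fixed_window | sliding_window
    window: int = 50_000
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("fixed_window", "sliding_window"):
            raise ValueError(f"unknown reassignment mode {self.mode!r}")
        if self.window <= 0:
            raise ValueError("window must be positive")


def _reassign(
    cat: MutationCatalogue, genome: Genome, scheme: ReassignmentScheme
) -> MutationCatalogue:
    rng = np.random.default_rng(scheme.seed)
    w = scheme.window
    out: list[MutationRecord] = []
    n_stuck = 0
    for r in cat.records:
        if r.chrom not in genome:
            logger.warning("mutation on unknown chromosome %s left in place", r.chrom)
            out.append(r)
            continue
        codes = genome.codes(r.chrom)
        target = codes[r.start] if 0 <= r.start < len(codes) else -1
        if target < 0:
            # no valid context at the origin (chromosome edge or ambiguous base)
            n_stuck += 1
            out.append(r)
            continue
        if scheme.mode == "fixed_window":
            lo = (r.start // w) * w
            hi = min(lo + w, len(codes))
        else:
            lo = max(r.start - w // 2, 0)
            hi = min(r.start + w // 2, len(codes))
        candidates = np.flatnonzero(codes[lo:hi] == target) + lo
        if candidates.size == 0:
            n_stuck += 1
            out.append(r)
            continue
        dest = int(rng.choice(candidates))
        shift = dest - r.start
        out.append(_dc_replace(r, start=dest, end=r.end + shift))
    if n_stuck:
        logger.info("%d mutations had no same-context destination and stayed in place",
                    n_stuck)
    return _dc_replace(cat, records=out)


def randomize_fixed_window(
    cat: MutationCatalogue, genome: Genome, scheme: ReassignmentScheme
) -> MutationCatalogue:
    """Reassign each mutation within its fixed genome-aligned partition."""
    if scheme.mode != "fixed_window":
        raise ValueError("scheme.mode must be 'fixed_window'")
    return _reassign(cat, genome, scheme)


def randomize_sliding_window(
    cat: MutationCatalogue, genome: Genome, scheme: ReassignmentScheme
) -> MutationCatalogue:
    """Reassign each mutation within a window centred on it (clipped to the
    chromosome)."""
    if scheme.mode != "sliding_window":
        raise ValueError("scheme.mode must be 'sliding_window'")
    return _reassign(cat, genome, scheme)
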