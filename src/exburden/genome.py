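"""In-memory genome sequence access with cached trinucleotide encoding.

Sequences are stored as uint8 arrays (A=0, C=1, G=2, T=3, anything else 4).
Each position's reference trinucleotide context (the base itself plus its
immediate 5' and 3' neighbours) is encoded as an integer in [0, 64):
``16*left + 4*centre + 1*right``. Positions whose context runs off the
chromosome or contains a non-ACGT base get code -1 and are ineligible for
profiling and subsampling.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

N_TRINUC = 64
TRINUCLEOTIDES = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


def encode_seq(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(enc: np.ndarray) -> str:
    return _DECODE[enc].tobytes().decode("ascii")


def trinuc_code(tri: str) -> int:
    """Integer code of a trinucleotide string, e.g. 'ACG' -> 6."""
    a, b, c = (BASES.index(x) for x in tri.upper())
    return 16 * a + 4 * b + c


def trinuc_str(code: int) -> str:
    return TRINUCLEOTIDES[code]


def trinuc_codes(enc: np.ndarray) -> np.ndarray:
    """Per-position context codes for an encoded chromosome; -1 = ineligible."""
    n = len(enc)
    codes = np.full(n, -1, dtype=np.int16)
    if n < 3:
        return codes
    left = enc[:-2].astype(np.int16)
    mid = enc[1:-1].astype(np.int16)
    right = enc[2:].astype(np.int16)
    valid = (left < 4) & (mid < 4) & (right < 4)
    inner = 16 * left + 4 * mid + right
    codes[1:-1] = np.where(valid, inner, -1)
    return codes


class Genome:
    """A set of named chromosome sequences with lazy context-code caches."""

    def __init__(self, seqs: dict[str, str]):
        self._enc = {c: encode_seq(s) for c, s in seqs.items()}
        self._codes: dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chroms(self) -> list[str]:
        return list(self._enc)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._enc

    def length(self, chrom: str) -> int:
        return len(self._enc[chrom])

    def lengths(self) -> dict[str, int]:
        return {c: len(e) for c, e in self._enc.items()}

    def encoded(self, chrom: str) -> np.ndarray:
        if chrom not in self._enc:
            raise KeyError(f"chromosome {chrom!r} not present in genome")
        return self._enc[chrom]

    def seq(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        return decode_seq(self.encoded(chrom)[start:end])

    def codes(self, chrom: str) -> np.ndarray:
        """Cached per-position trinucleotide context codes for ``chrom``."""
        if chrom not in self._codes:
            self._codes[chrom] = trinuc_codes(self.encoded(chrom))
        return self._codes[chrom]

    def write_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                fh.write(f">{chrom}\n")
                s = self.seq(chrom)
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")
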