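"""Gapped (k, g, l) sequence patterns ("MinSeqs") and DNA alphabet helpers.

A (k, g, l) pattern is a k-mer of specified bases, followed by a gap of
g unspecified positions, followed by an l-mer of specified bases.  The
canonical text form is ``LEFT-g-RIGHT`` (``LEFT`` alone for pure k-mers,
where g = 0 and the right part is empty).  Example: ``AACG-3-GCTTA`` is
the (4, 3, 5) pattern matching AACGNNNGCTTA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTNRYKMSWBDHVacgtn", "TGCANYRMKSWVHDBtgcan")

#: IUPAC degenerate nucleotide codes -> the set of concrete bases they admit.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_PATTERN_RE = re.compile(r"^([ACGT]+)(?:-(\d+)-([ACGT]+))?$")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True if ``seq`` (concrete) matches ``pattern`` (IUPAC) base by base."""
    if len(pattern) != len(seq):
        return False
    return all(s in IUPAC[p] for p, s in zip(pattern, seq))


def encode_reads(reads, length: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Encode equal-length DNA strings as a (N, L) uint8 array with A,C,G,T -> 0..3.

    Returns ``(array, valid)`` where ``valid`` marks reads free of non-ACGT
    characters (others get code 4 at the offending positions).  Reads with
    ambiguous bases are kept in the array so totals are preserved, but
    callers counting patterns should restrict to ``valid`` rows.
    """
    reads = list(reads)
    if length is None:
        length = len(reads[0]) if reads else 0
    lut = np.full(256, 4, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    if not reads:
        return np.zeros((0, length), dtype=np.uint8), np.zeros(0, dtype=bool)
    buf = np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8)
    arr = lut[buf].reshape(len(reads), length)
    valid = ~(arr == 4).any(axis=1)
    return arr, valid


def decode_kmer(code: int, n: int) -> str:
    out = []
    for j in range(n - 1, -1, -1):
        out.append(BASES[(code >> (2 * j)) & 3])
    return "".join(out)


@dataclass(frozen=True)
class MinSeqPattern:
    """A gapped (k, g, l) sequence pattern over {A, C, G, T}."""

    left: str
    gap: int = 0
    right: str = ""

    def __post_init__(self):
        if not self.left or any(b not in BASE_INDEX for b in self.left + self.right):
            raise ValueError(f"pattern bases must be in ACGT: {self.left!r}/{self.right!r}")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if not self.right and self.gap != 0:
            raise ValueError("a pure k-mer pattern must have gap 0")

    @property
    def k(self) -> int:
        return len(self.left)

    @property
    def g(self) -> int:
        return self.gap

    @property
    def l(self) -> int:
        return len(self.right)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.k, self.gap, self.l)

    @property
    def span(self) -> int:
        return self.k + self.gap + self.l

    @property
    def n_specified(self) -> int:
        return self.k + self.l

    @cached_property
    def text(self) -> str:
        if not self.right:
            return self.left
        return f"{self.left}-{self.gap}-{self.right}"

    def __str__(self) -> str:
        return self.text

    @classmethod
    def from_text(cls, text: str) -> "MinSeqPattern":
        m = _PATTERN_RE.match(text.strip().upper())
        if not m:
            raise ValueError(f"cannot parse pattern text: {text!r}")
        left, gap, right = m.groups()
        if gap is None:
            return cls(left)
        return cls(left, int(gap), right or "")

    @cached_property
    def spec_positions(self) -> np.ndarray:
        """Positions (relative to the pattern start) carrying specified bases."""
        return np.array(
            list(range(self.k)) + list(range(self.k + self.gap, self.span)), dtype=np.intp
        )

    @cached_property
    def spec_bases(self) -> np.ndarray:
        """Base codes (0..3) at the specified positions."""
        return np.array([BASE_INDEX[b] for b in self.left + self.right], dtype=np.uint8)

    @cached_property
    def code(self) -> int:
        """Integer code of the specified bases (base-4, left-to-right)."""
        c = 0
        for b in self.spec_bases:
            c = (c << 2) | int(b)
        return c

    def concrete(self) -> str:
        """The pattern as a plain string with the gap written as N's."""
        return self.left + "N" * self.gap + self.right

    def reverse_complement(self) -> "MinSeqPattern":
        return MinSeqPattern(revcomp(self.right), self.gap, revcomp(self.left)) \
            if self.right else MinSeqPattern(revcomp(self.left))

    def regex(self) -> re.Pattern:
        """Compiled regex matching the pattern on the given strand."""
        return re.compile(self.left + "." * self.gap + self.right)

    @classmethod
    def from_shape_code(cls, shape: tuple[int, int, int], code: int) -> "MinSeqPattern":
        k, g, l = shape
        s = decode_kmer(code, k + l)
        return cls(s[:k], g if l else 0, s[k:])
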