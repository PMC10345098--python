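"""Specificity and energy landscapes: SEL rings, gapped-SEL grids, DiSEL.

A SEL organizes all k-mers around a (possibly degenerate) seed in concentric
rings by minimal Hamming distance: ring 0 holds k-mers containing a perfect
seed match, ring m those whose best placement mismatches the seed at m
positions.  Within rings the ordering is deterministic: ring 0 sorts by the
bases flanking the seed and then by seed position; mismatch rings sort first
by the mismatch positions, then alphabetically by the substituted bases,
then by flanks and seed position.  Every k-mer appears exactly once.

Gapped SELs lay out the concrete expansions of a two-monomer degenerate seed
(DR / IR / ER arrangement) on a grid: row = gap length, column = the
substitution's index, identical for every gap so columns are comparable
across rows.  A DiSEL is the cell-wise difference of two max-normalized
landscapes, in [-1, 1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .patterns import IUPAC, MinSeqPattern, revcomp

GAP_CHARS = "n"


@dataclass(frozen=True)
class SelSeed:
    """A degenerate seed, optionally with explicit gap segments.

    Text forms: ``RGGTCA`` (plain), ``NRGGTCR-n-YGACCYN`` (one 1-nt gap),
    ``NRGGTCR-2-YGACCYN`` (digit form).  Gap segments are distinct from
    degenerate N positions: gaps stay symbolic during expansion.
    """

    text: str

    def __post_init__(self):
        for seg in self.segments:
            for i, c in enumerate(seg):
                if c not in IUPAC:
                    raise ValueError(f"invalid IUPAC code {c!r} at position {i} "
                                     f"of segment {seg!r}")

    @property
    def parts(self) -> tuple[list[str], list[int]]:
        """(segments, gaps) — gap tokens are digits or lowercase 'n' runs,
        e.g. ``A-2-B`` == ``A-nn-B``; adjacent segments imply gap 0."""
        segs, gaps = [], []
        for tok in self.text.split("-"):
            if tok.isdigit():
                gaps.append(int(tok))
            elif tok and set(tok) <= set(GAP_CHARS):
                gaps.append(len(tok))
            else:
                if len(segs) > len(gaps):   # two segments with no gap token
                    gaps.append(0)
                segs.append(tok.upper())
        return segs, gaps

    @property
    def segments(self) -> list[str]:
        return self.parts[0]

    @property
    def gaps(self) -> list[int]:
        return self.parts[1]

    @property
    def is_gapped(self) -> bool:
        return len(self.segments) > 1

    def degenerate_positions(self) -> list[tuple[int, int]]:
        """(segment index, position) of every non-ACGT code, left to right."""
        return [(si, i) for si, seg in enumerate(self.segments)
                for i, c in enumerate(seg) if len(IUPAC[c]) > 1]


def expand_degenerate_seed(seed: SelSeed | str) -> list[str]:
    """All concrete sequences matching the seed, lexicographic over the
    substituted (degenerate) positions; gap segments remain symbolic as
    ``-g-`` separators."""
    if isinstance(seed, str):
        seed = SelSeed(seed)
    segs, gaps = seed.parts
    degen = seed.degenerate_positions()
    choices = [sorted(IUPAC[segs[si][i]]) for si, i in degen]
    out = []
    for combo in itertools.product(*choices):
        parts = [list(s) for s in segs]
        for (si, i), b in zip(degen, combo):
            parts[si][i] = b
        texts = ["".join(p) for p in parts]
        merged = texts[0]
        for g, nxt in zip(gaps, texts[1:]):
            merged += f"-{g}-{nxt}" if g else nxt
        out.append(merged)
    return out


# ---------------------------------------------------------------------------
# concentric-ring SEL

@dataclass
class SelRing:
    mismatch: int
    sequences: list[str]
    values: np.ndarray


@dataclass
class SelLandscape:
    seed: SelSeed
    rings: list[SelRing]

    def ring(self, m: int) -> SelRing:
        return self.rings[m]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"ring": r.mismatch, "index": i, "sequence": s, "enrichment": v}
                for r in self.rings
                for i, (s, v) in enumerate(zip(r.sequences, r.values))]
        return pd.DataFrame(rows)


def _best_placement(kmer: str, seed: str) -> tuple[int, int, tuple, tuple, str]:
    """Minimal-mismatch placement of ``seed`` inside ``kmer``.

    Returns (mismatches, offset, mismatch positions, substituted bases,
    flanks); ties among offsets break leftmost.
    """
    best = None
    for off in range(len(kmer) - len(seed) + 1):
        mm = tuple(i for i in range(len(seed))
                   if kmer[off + i] not in IUPAC[seed[i]])
        subs = tuple(kmer[off + i] for i in mm)
        flanks = kmer[:off] + kmer[off + len(seed):]
        cand = (len(mm), off, mm, subs, flanks)
        if best is None or cand[0] < best[0]:
            best = cand
    return best


def build_sel(seed: SelSeed | str, scores: dict[str, float],
              max_ring: int | None = None) -> SelLandscape:
    """Assign every supplied k-mer to its mismatch ring and order the rings.

    ``scores`` maps equal-length k-mers to enrichment values.  Each k-mer
    lands in exactly one ring (its minimal mismatch count over placements).
    """
    if isinstance(seed, str):
        seed = SelSeed(seed)
    if seed.is_gapped:
        raise ValueError("ring SELs take ungapped seeds; use build_gapped_sel")
    stext = seed.segments[0]
    kmers = list(scores)
    if not kmers:
        return SelLandscape(seed, [])
    klen = len(kmers[0])
    if any(len(s) != klen for s in kmers):
        raise ValueError("all k-mers must have equal length")
    if len(stext) > klen:
        raise ValueError("seed longer than the k-mers")
    placed: dict[int, list] = {}
    for kmer in kmers:
        mm, off, pos, subs, flanks = _best_placement(kmer, stext)
        placed.setdefault(mm, []).append(((pos, subs, flanks, off), kmer))
    rings = []
    top = max(placed) if max_ring is None else min(max(placed), max_ring)
    for m in range(top + 1):
        entries = sorted(placed.get(m, []))
        seqs = [k for _, k in entries]
        rings.append(SelRing(m, seqs, np.array([scores[s] for s in seqs])))
    return SelLandscape(seed, rings)


# ---------------------------------------------------------------------------
# gapped-SEL grids

def dimer_seed(monomer: str, arrangement: str, gap: int,
               flank_n: int = 1) -> SelSeed:
    """Two-monomer degenerate seed for one arrangement and gap.

    DR: monomer...monomer; IR: monomer...revcomp; ER: revcomp...monomer —
    each wrapped in ``flank_n`` N's, e.g. IR1 of RGGTCR -> NRGGTCR-1-YGACCYN.
    """
    if arrangement not in ("DR", "IR", "ER"):
        raise ValueError(f"unknown arrangement {arrangement!r}")
    m = monomer.upper()
    rc = revcomp(m)
    left, right = {"DR": (m, m), "IR": (m, rc), "ER": (rc, m)}[arrangement]
    n = "N" * flank_n
    text = f"{n}{left}-{gap}-{right}{n}" if gap else f"{n}{left}{right}{n}"
    return SelSeed(text)


def build_gapped_sel(monomer: str, arrangement: str, scores,
                     gaps=range(0, 9), flank_n: int = 1,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grid of enrichments: rows = gap length, columns = substitution index.

    ``scores`` is a mapping from concrete (gapped) sequence text to
    enrichment, or a callable applied to each text.  A given substitution
    keeps the same column at every gap.  Returns (grid, sequences) frames;
    sequences missing from a mapping score 0 (they stay visible as columns).
    """
    lookup = scores if callable(scores) else \
        (lambda t: scores.get(t, 0.0))
    grid_rows, seq_rows = {}, {}
    for g in gaps:
        seed = dimer_seed(monomer, arrangement, g, flank_n)
        texts = expand_degenerate_seed(seed)
        grid_rows[g] = [float(lookup(t)) for t in texts]
        seq_rows[g] = texts
    grid = pd.DataFrame.from_dict(grid_rows, orient="index")
    grid.index.name = "gap"
    seqs = pd.DataFrame.from_dict(seq_rows, orient="index")
    seqs.index.name = "gap"
    return grid, seqs


# ---------------------------------------------------------------------------
# DiSEL

def _values_of(obj) -> np.ndarray:
    if isinstance(obj, SelLandscape):
        return np.concatenate([r.values for r in obj.rings]) if obj.rings \
            else np.zeros(0)
    if isinstance(obj, pd.DataFrame):
        return obj.to_numpy(dtype=float)
    return np.asarray(obj, dtype=float)


def disel(a, b):
    """Difference landscape: max-normalize each input to 1, then a - b.

    Accepts two grids (DataFrames / arrays) or two SelLandscapes of identical
    shape; values land in [-1, 1].  DiSEL of A over B shows binding preferred
    by A.
    """
    if isinstance(a, SelLandscape) and isinstance(b, SelLandscape):
        if [len(r.sequences) for r in a.rings] != [len(r.sequences) for r in b.rings]:
            raise ValueError("landscape shapes differ")
        norm_a = max(_values_of(a).max(), 0) or 1.0
        norm_b = max(_values_of(b).max(), 0) or 1.0
        rings = [SelRing(ra.mismatch, ra.sequences,
                         ra.values / norm_a - rb.values / norm_b)
                 for ra, rb in zip(a.rings, b.rings)]
        return SelLandscape(a.seed, rings)
    va, vb = _values_of(a), _values_of(b)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch {va.shape} vs {vb.shape}")
    norm_a = va.max() if va.size and va.max() > 0 else 1.0
    norm_b = vb.max() if vb.size and vb.max() > 0 else 1.0
    diff = va / norm_a - vb / norm_b
    if isinstance(a, pd.DataFrame):
        return pd.DataFrame(diff, index=a.index, columns=a.columns)
    return diff


def kmer_scores_from_model(model, k: int) -> dict[str, float]:
    """Enrichment of every k-mer under a scoring model (for SEL input).

    Exhaustive over 4**k sequences — intended for k <= 8.
    """
    from .annotate import score_sequence
    from .patterns import BASES
    out = {}
    for combo in itertools.product(BASES, repeat=k):
        s = "".join(combo)
        out[s] = score_sequence(model, s)
    return out
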