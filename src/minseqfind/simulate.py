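"""Synthetic HT-SELEX: round-0 libraries and multi-round affinity selection.

The generator emulates a 20-nt random-region SELEX experiment: a round-0
library of ``library_size`` reads, followed by ``rounds`` rounds in which the
previous pool is resampled with replacement, each read weighted by
affinity ** selection_sharpness (resampling stands in for bind-wash-amplify).

A real SELEX library (~1e12 molecules over 4**20 sequences) contains every
cognate site at low frequency even though a sequencing-depth-sized sample
rarely does.  Because selection here acts on the sampled pool, the generator
reintroduces that molecular diversity by seeding each planted pattern into
the library at a small ``site_frequency`` (default 1e-3 of reads carry one
planted instance at a random offset and strand); selection then amplifies
carriers over rounds exactly as the bound fraction grows in the experiment.
With no planted patterns (or all affinities equal) every round is a plain
resample of the library.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .patterns import BASES, MinSeqPattern, revcomp
from .seqio import ReadSet, write_fasta, write_fastq


@dataclass
class SimConfig:
    """Study conditions for a synthetic SELEX run.

    Defaults mirror a desk-scale experiment: 20-nt variable region, 1e5 reads
    per round, 3 selection rounds, one planted gapped site at 20x relative
    affinity, proportional (soft) selection.
    """

    read_length: int = 20
    library_size: int = 100_000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted: list[tuple[MinSeqPattern, float]] = field(
        default_factory=lambda: [(MinSeqPattern.from_text("AGGTCA-1-AGGTCA"), 20.0)])
    rounds: int = 3
    depth: int = 100_000
    selection_sharpness: float = 1.0
    site_frequency: float = 1e-3
    seed: int = 0
    gc_bias: float = 0.0   # optional per-read GC multiplier exponent (off by default)

    def __post_init__(self):
        if any(a <= 0 for _, a in self.planted):
            raise ValueError("planted affinities must be > 0")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("base_composition must be 4 probabilities summing to 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _random_reads(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(4, size=(n, config.read_length),
                      p=np.asarray(config.base_composition)).astype(np.uint8)


def _implant(arr: np.ndarray, pattern: MinSeqPattern, rows: np.ndarray,
             rng: np.random.Generator) -> None:
    """Write a concrete instance of ``pattern`` into each row in place."""
    span = pattern.span
    L = arr.shape[1]
    for row in rows:
        site = list(pattern.spec_bases)
        text = pattern.left + "".join(BASES[rng.integers(4)] for _ in range(pattern.gap)) \
            + pattern.right
        if rng.integers(2):
            text = revcomp(text)
        off = rng.integers(L - span + 1)
        arr[row, off:off + span] = [BASES.index(c) for c in text]


def _decode(arr: np.ndarray) -> list[str]:
    letters = np.array(list(BASES), dtype="U1")
    return ["".join(row) for row in letters[arr]]


def simulate_library(config: SimConfig, rng: np.random.Generator | None = None
                     ) -> ReadSet:
    """Round-0 library: background composition plus low-frequency planted sites."""
    rng = config.rng() if rng is None else rng
    arr = _random_reads(config, config.library_size, rng)
    for pattern, _aff in config.planted:
        carriers = np.flatnonzero(rng.random(config.library_size) < config.site_frequency)
        _implant(arr, pattern, carriers, rng)
    return ReadSet(_decode(arr), read_length=config.read_length, name="round0")


def _contains_encoded(arr: np.ndarray, pattern: MinSeqPattern) -> np.ndarray:
    """Boolean per-read containment of ``pattern`` on either strand."""
    L = arr.shape[1]
    hit = np.zeros(arr.shape[0], dtype=bool)
    for pat in (pattern, pattern.reverse_complement()):
        span = pat.span
        if span > L:
            continue
        pos, bases = pat.spec_positions, pat.spec_bases
        for off in range(L - span + 1):
            m = np.ones(arr.shape[0], dtype=bool)
            for p, b in zip(pos, bases):
                m &= arr[:, off + p] == b
                if not m.any():
                    break
            hit |= m
    return hit


def affinity_of(config: SimConfig, seq: str) -> float:
    """Relative affinity of one read: max planted affinity contained (either
    strand), baseline 1 when no planted pattern matches."""
    best = 1.0
    for pattern, aff in config.planted:
        for pat in (pattern, pattern.reverse_complement()):
            if pat.regex().search(seq.upper()):
                best = max(best, aff)
                break
    return best


def _affinities(config: SimConfig, arr: np.ndarray) -> np.ndarray:
    aff = np.ones(arr.shape[0])
    for pattern, a in config.planted:
        hit = _contains_encoded(arr, pattern)
        aff[hit] = np.maximum(aff[hit], a)
    if config.gc_bias:
        gc = ((arr == 1) | (arr == 2)).mean(axis=1)
        aff *= np.exp(config.gc_bias * (gc - 0.5))
    return aff


def simulate_selex(config: SimConfig) -> list[ReadSet]:
    """Run the full simulation; returns [round0, round1, ..., roundR].

    Each round draws ``depth`` reads with replacement from the previous pool
    with probability proportional to affinity ** selection_sharpness.
    """
    rng = config.rng()
    library = simulate_library(config, rng)
    pools = [library]
    arr, _ = library.encoded()
    arr = arr.copy()
    for r in range(1, config.rounds + 1):
        w = _affinities(config, arr) ** config.selection_sharpness
        idx = rng.choice(arr.shape[0], size=config.depth, p=w / w.sum())
        arr = arr[idx]
        pools.append(ReadSet(_decode(arr), read_length=config.read_length,
                             name=f"round{r}"))
    return pools


def library_diversity(read_length: int = 20) -> float:
    """Theoretical sequence diversity of the random region, 4**L."""
    return float(4 ** read_length)


def write_simulation(pools: list[ReadSet], config: SimConfig, out_dir,
                     format: str = "fastq") -> None:
    """Write per-round reads plus a ground-truth JSON (plants, affinities, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    writer = write_fastq if format == "fastq" else write_fasta
    for pool in pools:
        writer(pool, out / f"{pool.name}.{format}")
    truth = {
        "seed": config.seed,
        "read_length": config.read_length,
        "rounds": config.rounds,
        "site_frequency": config.site_frequency,
        "selection_sharpness": config.selection_sharpness,
        "planted": [{"pattern": p.text, "affinity": a} for p, a in config.planted],
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
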