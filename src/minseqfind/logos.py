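"""Iterative PWM (sequence logo) extraction from a ranked MinSeq table.

The top-ranked MinSeq seeds a position weight matrix: the seed is extended
by 6 N positions on each side, and at every position each of A, C, G, T is
substituted in turn; each single-substitution pattern is counted in the
bound reads and normalized to the library model, giving four enrichment
values per column that are normalized to probabilities.  All records are
then re-scored against the PWMs obtained so far, the best PWM estimate is
subtracted from each record's weighted enrichment, the table is re-ranked
on the residual, and the next seed is taken — until the iteration cap or a
minimum residual is reached.

Substitution windows that would extend past the read boundary are counted
only where they fit (normalization is per expected count, so partial
occupancy cancels); a fully unfittable column falls back to uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paglo import PagloModel
from .patterns import BASES, MinSeqPattern
from .seqio import ReadSet

N_EXTEND = 6  # N positions added on each side of the seed


@dataclass
class PositionWeightMatrix:
    """Per-position base probabilities derived from an enrichment scan.

    ``weights`` is (width, 4) with rows summing to 1; ``gap_mask`` marks
    columns inside the seed's spacer (kept uniform); ``seed_weighted`` is the
    seed record's weighted enrichment, the scale for PWM-based estimates.
    """

    weights: np.ndarray
    seed: MinSeqPattern
    gap_mask: np.ndarray
    seed_weighted: float = 0.0
    seed_enrichment: float = 0.0

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    @property
    def core_start(self) -> int:
        return N_EXTEND

    def consensus(self, core_only: bool = True, gap_char: str = "N") -> str:
        """Argmax base per column; spacer columns rendered as ``gap_char``."""
        idx = np.argmax(self.weights, axis=1)
        chars = [gap_char if self.gap_mask[i] else BASES[idx[i]]
                 for i in range(self.width)]
        if core_only:
            chars = chars[N_EXTEND:self.width - N_EXTEND]
        return "".join(chars)

    def odds(self, position: int, base_code: int) -> float:
        return self.weights[position, base_code] / 0.25


@dataclass
class LogoSet:
    pwms: list[PositionWeightMatrix]
    residual_trace: list[float] = field(default_factory=list)
    stop_reason: str = ""

    def __len__(self):
        return len(self.pwms)


def _masked_count(arr: np.ndarray, positions: np.ndarray, bases: np.ndarray
                  ) -> tuple[int, int]:
    """Occurrences of a masked pattern over all fitting offsets.

    Returns (count, n_offsets) where positions are relative to the pattern
    start; negative positions shift the viable offset range.
    """
    L = arr.shape[1]
    lo, hi = int(positions.min()), int(positions.max())
    count = 0
    n_off = 0
    for off in range(-lo, L - hi):
        m = np.ones(arr.shape[0], dtype=bool)
        for p, b in zip(positions, bases):
            m &= arr[:, off + p] == b
        count += int(m.sum())
        n_off += 1
    return count, n_off


def build_pwm_from_seed(seed: MinSeqPattern, bound: ReadSet, model: PagloModel,
                        seed_weighted: float = 0.0, seed_enrichment: float = 0.0,
                        ) -> PositionWeightMatrix:
    """Enrichment scan around a seed: one PWM column per extended position.

    For each position of the N-extended seed and each base, the
    single-substitution pattern is counted in the bound reads and divided by
    its expected frequency under the library model; the four enrichments are
    normalized to a probability column.  Spacer columns stay uniform.
    """
    arr, valid = bound.encoded()
    arr = arr[valid].astype(np.int64)
    if arr.shape[0] == 0:
        raise ValueError("no unambiguous bound reads")
    L = bound.read_length
    span = seed.span
    width = span + 2 * N_EXTEND
    core_pos = seed.spec_positions            # relative to seed start
    core_bases = seed.spec_bases.astype(np.intp)
    base_count, _ = _masked_count(arr, core_pos, core_bases)
    if base_count == 0:
        raise ValueError(f"seed unsupported: {seed.text} absent from bound reads")

    gap_mask = np.zeros(width, dtype=bool)
    gap_mask[N_EXTEND + seed.k:N_EXTEND + seed.k + seed.gap] = True
    weights = np.full((width, 4), 0.25)
    T_b = bound.total_reads

    for col in range(width):
        rel = col - N_EXTEND                  # position relative to seed start
        if gap_mask[col]:
            continue
        enrich = np.zeros(4)
        for b in range(4):
            if 0 <= rel < span and rel in core_pos:
                j = int(np.where(core_pos == rel)[0][0])
                positions = core_pos
                bases = core_bases.copy()
                bases[j] = b
            else:
                positions = np.append(core_pos, rel)
                bases = np.append(core_bases, b)
                order = np.argsort(positions)
                positions, bases = positions[order], bases[order]
            span_here = int(positions.max() - positions.min()) + 1
            if span_here > L:
                enrich[:] = 1.0               # nothing fits: neutral column
                break
            count, _ = _masked_count(arr, positions, bases)
            shifted = positions - positions.min()
            probs = [model.masked_probability_batch(shifted, bases[None, :], off)[0]
                     for off in range(L - span_here + 1)]
            expected = model.T * float(np.sum(probs))
            enrich[b] = (count / T_b) / (expected / model.T) if expected > 0 else 0.0
        total = enrich.sum()
        if total > 0:
            weights[col] = enrich / total
    return PositionWeightMatrix(weights=weights, seed=seed, gap_mask=gap_mask,
                                seed_weighted=seed_weighted,
                                seed_enrichment=seed_enrichment)


def pwm_estimate(pattern: MinSeqPattern, pwms: list[PositionWeightMatrix]) -> float:
    """Best PWM-based estimate of a pattern's (raw) enrichment.

    For each PWM and each alignment of the pattern (or its reverse
    complement — counting is single-strand, so a motif and its complement
    are the same binding event) inside the PWM window, the product of
    per-position odds (weight / 0.25) over the pattern's specified positions
    is taken, skipping PWM spacer columns; the product is scaled so the
    PWM's own seed maps to its seed enrichment.  Returns the max over PWMs,
    strands and alignments, 0 when nothing fits.
    """
    if not pwms:
        return 0.0
    best = 0.0
    orientations = [pattern, pattern.reverse_complement()]
    for pwm in pwms:
        seed_odds = 1.0
        off0 = N_EXTEND
        for p, b in zip(pwm.seed.spec_positions, pwm.seed.spec_bases):
            seed_odds *= pwm.odds(off0 + int(p), int(b))
        if seed_odds <= 0:
            continue
        scale = pwm.seed_enrichment / seed_odds
        for pat in orientations:
            for off in range(pwm.width - pat.span + 1):
                odds = 1.0
                for p, b in zip(pat.spec_positions, pat.spec_bases):
                    col = off + int(p)
                    if pwm.gap_mask[col]:
                        continue
                    odds *= pwm.odds(col, int(b))
                best = max(best, scale * odds)
    return best


def estimate_weighted(pattern: MinSeqPattern,
                      pwms: list[PositionWeightMatrix]) -> float:
    """PWM estimate converted to weighted-enrichment units,
    log2(max(estimate, 1)) / (k + l), commensurate with W(x)."""
    est = pwm_estimate(pattern, pwms)
    return float(np.log2(max(est, 1.0)) / pattern.n_specified)


def extract_logos(table, bound: ReadSet, model: PagloModel,
                  max_iter: int = 10, min_residual: float | None = None,
                  min_residual_frac: float = 0.05) -> LogoSet:
    """Iteratively extract PWMs from the ranked table with residual subtraction.

    ``min_residual`` defaults to ``min_residual_frac`` of the initial total
    weighted enrichment.  Residual subtraction operates in weighted units:
    residual(x) = max(0, W(x) - best PWM estimate of x converted to weighted
    units) — so a PWM suppresses its own seed, the seed's sub-patterns and
    near-variants, and the next iteration seeds on genuinely unexplained
    signal.
    """
    ranked = table.ranked()
    records = ranked[ranked.weighted.notna() & (ranked.weighted > 0)]
    if len(records) == 0 or max_iter == 0:
        return LogoSet([], [], stop_reason="max_iter" if max_iter == 0 else "empty")
    patterns = [MinSeqPattern.from_text(t) for t in records.pattern]
    residual = records.weighted.to_numpy(dtype=float).copy()
    enrichment = records.enrichment.to_numpy(dtype=float)
    initial_total = float(residual.sum())
    if min_residual is None:
        min_residual = min_residual_frac * initial_total
    pwms: list[PositionWeightMatrix] = []
    trace: list[float] = []
    stop = "max_iter"
    order = np.lexsort((records.pattern.to_numpy(), -enrichment, -residual))
    for _ in range(max_iter):
        top = int(order[0])
        if residual[top] <= 0:
            stop = "min_residual"
            break
        pwm = build_pwm_from_seed(patterns[top], bound, model,
                                  seed_weighted=float(records.weighted.iloc[top]),
                                  seed_enrichment=float(enrichment[top]))
        pwms.append(pwm)
        estimates = np.array([estimate_weighted(p, pwms) for p in patterns])
        residual = np.maximum(0.0, records.weighted.to_numpy(dtype=float) - estimates)
        trace.append(float(residual.sum()))
        order = np.lexsort((records.pattern.to_numpy(), -enrichment, -residual))
        if trace[-1] <= min_residual:
            stop = "min_residual"
            break
    return LogoSet(pwms, trace, stop_reason=stop)


def write_meme(pwms: list[PositionWeightMatrix], path,
               background: tuple[float, float, float, float] = (0.25,) * 4) -> None:
    """Write PWMs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(background))
        for i, pwm in enumerate(pwms, 1):
            fh.write(f"MOTIF {pwm.seed.text} MS{i}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= 20 E= 0\n")
            for row in pwm.weights:
                fh.write(" %.6f %.6f %.6f %.6f\n" % tuple(row))
            fh.write("\n")


def read_meme(path) -> list[np.ndarray]:
    """Read letter-probability matrices back from a MEME minimal file."""
    mats, current = [], None
    for line in open(path):
        if line.startswith("letter-probability matrix"):
            current = []
        elif current is not None:
            vals = line.split()
            if len(vals) == 4:
                current.append([float(v) for v in vals])
            else:
                mats.append(np.array(current))
                current = None
    if current:
        mats.append(np.array(current))
    return mats
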