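"""MinSeq Find core: gapped (k, g, l) pattern counting, count thresholding,
enrichment against the PAGLO library model, length weighting, and sparse
reduction by a modified orthogonal matching pursuit (OMP).

The enrichment of a pattern x is

    E*(x) = (C_b(x) / T_b) / (C*(x) / T)

where C_b is the pattern's count in the bound reads, T_b the total bound
reads, C* the expected count under the library model and T the total library
reads.  Weighted enrichment W(x) = log2(E*(x)) / (k + l) makes patterns of
different specified lengths commensurable (per specified base).
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import poisson

from .paglo import PagloModel
from .patterns import BASES, MinSeqPattern, revcomp
from .seqio import ReadSet

_LETTERS = np.array(list(BASES), dtype="U1")


# ---------------------------------------------------------------------------
# shape configuration

@dataclass(frozen=True)
class ShapeConfig:
    """Ranges of (k, g, l) shapes to enumerate.

    Defaults: half lengths k, l in 3..8 (plus pure k-mers with l = 0),
    gaps 0..8, total span capped at the read length.
    """

    k_min: int = 3
    k_max: int = 8
    l_min: int = 3
    l_max: int = 8
    g_min: int = 0
    g_max: int = 8
    max_span: int = 20
    pure_kmers: bool = True

    def shapes(self, read_length: int | None = None) -> list[tuple[int, int, int]]:
        cap = self.max_span if read_length is None else min(self.max_span, read_length)
        out = []
        if self.pure_kmers:
            out += [(k, 0, 0) for k in range(self.k_min, self.k_max + 1) if k <= cap]
        for k in range(self.k_min, self.k_max + 1):
            for l in range(self.l_min, self.l_max + 1):
                for g in range(self.g_min, self.g_max + 1):
                    if k + g + l <= cap:
                        out.append((k, g, l))
        return out

    def describe(self) -> str:
        return (f"k={self.k_min}..{self.k_max},l={self.l_min}..{self.l_max},"
                f"g={self.g_min}..{self.g_max},span<={self.max_span},"
                f"pure_kmers={self.pure_kmers}")


# ---------------------------------------------------------------------------
# counting

@dataclass
class PatternCounts:
    """Per-shape sparse pattern counts from a bound read set.

    ``counts[shape]`` is a pair (codes, n) of sorted base-4 integer codes of
    the specified bases and their occurrence counts.
    """

    counts: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]]
    read_length: int
    n_reads_counted: int       # unambiguous reads actually scanned
    total_reads: int           # T_b, includes reads flagged for ambiguity
    effective_threshold: dict[tuple[int, int, int], int] = field(default_factory=dict)

    def shape_total(self, shape) -> int:
        return int(self.counts[shape][1].sum())

    def get(self, pattern: MinSeqPattern) -> int:
        shape = pattern.shape
        if shape not in self.counts:
            return 0
        codes, n = self.counts[shape]
        i = np.searchsorted(codes, pattern.code)
        if i < len(codes) and codes[i] == pattern.code:
            return int(n[i])
        return 0


def _window_codes(arr: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Base-4 codes of every (read, offset) window for one shape: (N, W) int64."""
    k, g, l = shape
    L = arr.shape[1]
    span = k + g + l
    positions = np.array(list(range(k)) + list(range(k + g, span)), dtype=np.intp)
    offsets = np.arange(L - span + 1)
    codes = np.zeros((arr.shape[0], len(offsets)), dtype=np.int64)
    for p in positions:
        codes <<= 2
        codes += arr[:, offsets + p]
    return codes


def enumerate_and_count(bound: ReadSet, shapes: ShapeConfig | list = ShapeConfig()
                        ) -> PatternCounts:
    """Bin and count every sub-sequence of every bound read in each shape class.

    Each window of each read increments exactly one pattern per shape, so the
    per-shape total equals n_reads * (L - span + 1).  Reads containing
    ambiguous bases are skipped for counting but still appear in T_b.
    """
    L = bound.read_length
    shape_list = shapes.shapes(L) if isinstance(shapes, ShapeConfig) else list(shapes)
    arr, valid = bound.encoded()
    arr = arr[valid].astype(np.int64)
    counts = {}
    for shape in shape_list:
        if sum(shape) > L:
            warnings.warn(f"shape {shape} span exceeds read length {L}; skipped",
                          stacklevel=2)
            continue
        codes, n = np.unique(_window_codes(arr, shape).ravel(), return_counts=True)
        counts[shape] = (codes, n)
    return PatternCounts(counts=counts, read_length=L,
                         n_reads_counted=arr.shape[0], total_reads=bound.total_reads)


# ---------------------------------------------------------------------------
# thresholding

@dataclass(frozen=True)
class ThresholdPolicy:
    """Count threshold C^T below which patterns are discarded (C_b >= C^T keeps).

    ``absolute`` mode uses the fixed C_T.  ``poisson`` mode derives, per shape
    class, the smallest c with P(Poisson(lambda) >= c) <= alpha / M where
    lambda is the class null mean count (windows / 4**(k+l)) and M the total
    number of patterns across *all* enumerated shape classes (global
    Bonferroni), so a signal-free run retains nothing with probability about
    1 - alpha.
    """

    mode: str = "absolute"
    C_T: int = 10
    alpha: float = 0.01

    def __post_init__(self):
        if self.mode not in ("absolute", "poisson"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.C_T < 1:
            raise ValueError("C_T must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def describe(self) -> str:
        return (f"absolute:{self.C_T}" if self.mode == "absolute"
                else f"poisson:{self.alpha}")


def poisson_threshold(lam: float, M: int, alpha: float) -> int:
    """Smallest c with upper-tail P(X >= c) <= alpha / M for X ~ Poisson(lam)."""
    c = int(poisson.ppf(1.0 - alpha / M, lam)) + 1
    while c > 1 and poisson.sf(c - 2, lam) <= alpha / M:
        c -= 1
    return max(c, 1)


def apply_threshold(raw: PatternCounts, policy: ThresholdPolicy = ThresholdPolicy()
                    ) -> PatternCounts:
    """Discard patterns with count below the (per-shape) effective C^T."""
    out: dict = {}
    eff: dict = {}
    M_total = sum(4 ** (k + l) for (k, g, l) in raw.counts)
    for shape, (codes, n) in raw.counts.items():
        if policy.mode == "absolute":
            c_t = policy.C_T
        else:
            span = sum(shape)
            windows = raw.n_reads_counted * (raw.read_length - span + 1)
            c_t = poisson_threshold(windows / 4 ** (shape[0] + shape[2]),
                                    M_total, policy.alpha)
        keep = n >= c_t
        out[shape] = (codes[keep], n[keep])
        eff[shape] = c_t
    return PatternCounts(counts=out, read_length=raw.read_length,
                         n_reads_counted=raw.n_reads_counted,
                         total_reads=raw.total_reads, effective_threshold=eff)


# ---------------------------------------------------------------------------
# enrichment table

class MinSeqTable:
    """A table of MinSeq records with counts, expected counts and enrichments.

    Wraps a pandas DataFrame with columns: pattern, k, g, l, C_b, C_expected,
    enrichment, weighted, omp_weight (NaN until OMP), low_expected flag.
    """

    COLUMNS = ["pattern", "k", "g", "l", "C_b", "C_expected",
               "enrichment", "weighted", "omp_weight", "low_expected"]

    def __init__(self, df: pd.DataFrame, T_b: int, T: int,
                 policy: str = "", shape_config: str = "", name: str = ""):
        self.df = df
        self.T_b = T_b
        self.T = T
        self.policy = policy
        self.shape_config = shape_config
        self.name = name

    def __len__(self):
        return len(self.df)

    def ranked(self) -> pd.DataFrame:
        """Rankable records (positive enrichment, adequate expected count)."""
        d = self.df
        return d[(~d.low_expected) & (d.enrichment > 0)]

    def top(self, n: int, by: str = "auto") -> pd.DataFrame:
        """Top-n records, preferring OMP weights when present."""
        d = self.ranked()
        if by == "auto":
            by = "omp_weight" if d.omp_weight.notna().any() else "weighted"
        if by == "omp_weight":
            d = d[d.omp_weight.notna() & (d.omp_weight > 0)]
        return d.sort_values([by, "enrichment", "pattern"],
                             ascending=[False, False, True]).head(n)

    def patterns(self, df: pd.DataFrame | None = None) -> list[MinSeqPattern]:
        d = self.df if df is None else df
        return [MinSeqPattern.from_text(t) for t in d.pattern]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# minseqfind table\tname={self.name}\tT_b={self.T_b}\t"
                     f"T={self.T}\tpolicy={self.policy}\tshapes={self.shape_config}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MinSeqTable":
        meta = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first.lstrip("#").strip().split("\t"):
                    if "=" in tok:
                        key, v = tok.split("=", 1)
                        meta[key] = v
                body = fh.read()
            else:
                body = first + fh.read()
        df = pd.read_csv(io.StringIO(body), sep="\t")
        if "low_expected" in df:
            df["low_expected"] = df["low_expected"].astype(bool)
        return cls(df, T_b=int(meta.get("T_b", 0)), T=int(meta.get("T", 0)),
                   policy=meta.get("policy", ""), shape_config=meta.get("shapes", ""),
                   name=meta.get("name", ""))


def _codes_to_text(codes: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    k, g, l = shape
    n = k + l
    shifts = np.arange(n - 1, -1, -1) * 2
    chars = _LETTERS[(codes[:, None] >> shifts[None, :]) & 3]
    full = np.ascontiguousarray(chars).view(f"U{n}")[:, 0]
    if l == 0:
        return full
    left = np.ascontiguousarray(chars[:, :k]).view(f"U{k}")[:, 0]
    right = np.ascontiguousarray(chars[:, k:]).view(f"U{l}")[:, 0]
    mid = np.full(len(codes), f"-{g}-", dtype=f"U{len(str(g)) + 2}")
    return np.char.add(np.char.add(left, mid), right)


def compute_enrichment(filtered: PatternCounts, model: PagloModel,
                       T_b: int | None = None, expected_floor: float = 0.01,
                       name: str = "") -> MinSeqTable:
    """Build the MinSeq table: E*(x) = (C_b/T_b) / (C*/T) for retained patterns.

    Patterns whose expected count falls below ``expected_floor`` are flagged
    (``low_expected``) and excluded from ranking rather than producing
    numerically degenerate enrichments.  The default floor (0.01 expected
    reads) is low enough that long, specific patterns stay rankable — a
    threshold-passing count of 10+ occurrences at this floor cannot be
    Poisson background — while true division blowups are still caught.
    """
    if model.T == 0:
        raise ValueError("library model has T = 0")
    if model.read_length != filtered.read_length:
        raise ValueError("model read length does not match counted reads")
    T_b = filtered.total_reads if T_b is None else T_b
    if T_b <= 0:
        raise ValueError("T_b must be positive")
    frames = []
    for shape, (codes, n) in filtered.counts.items():
        if len(codes) == 0:
            continue
        expected = model.expected_counts_batch(shape, codes)
        low = expected < expected_floor
        with np.errstate(divide="ignore", invalid="ignore"):
            enr = np.where(low, 0.0, (n / T_b) / (expected / model.T))
        frames.append(pd.DataFrame({
            "pattern": _codes_to_text(codes, shape),
            "k": shape[0], "g": shape[1], "l": shape[2],
            "C_b": n, "C_expected": expected,
            "enrichment": enr, "low_expected": low,
        }))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=[c for c in MinSeqTable.COLUMNS
                                   if c not in ("weighted", "omp_weight")])
    df["weighted"] = np.nan
    df["omp_weight"] = np.nan
    policy = ""
    if filtered.effective_threshold:
        policy = ";".join(f"{s}:{c}" for s, c in
                          sorted(filtered.effective_threshold.items()))
    return MinSeqTable(df[MinSeqTable.COLUMNS], T_b=T_b, T=model.T,
                       policy=policy, name=name)


def weight_enrichment(table: MinSeqTable) -> MinSeqTable:
    """Length-weight enrichments, W(x) = log2(E*) / (k + l), and rank the table.

    Ties in W break by raw enrichment, then by pattern text, so the ranking is
    independent of input order.  Records with E* <= 0 (or flagged expected
    counts) get no weight and sort last.
    """
    df = table.df.copy()
    ok = (df.enrichment > 0) & (~df.low_expected)
    with np.errstate(divide="ignore"):
        df.loc[ok, "weighted"] = (np.log2(df.loc[ok, "enrichment"])
                                  / (df.loc[ok, "k"] + df.loc[ok, "l"]))
    df = df.sort_values(["weighted", "enrichment", "pattern"],
                        ascending=[False, False, True],
                        na_position="last", kind="mergesort").reset_index(drop=True)
    return MinSeqTable(df, T_b=table.T_b, T=table.T, policy=table.policy,
                       shape_config=table.shape_config, name=table.name)


def find_minseqs(bound: ReadSet, model: PagloModel,
                 shapes: ShapeConfig = ShapeConfig(),
                 policy: ThresholdPolicy = ThresholdPolicy(),
                 expected_floor: float = 0.01, name: str = "") -> MinSeqTable:
    """The full MinSeq Find pass: count, threshold, enrich, weight, rank."""
    raw = enumerate_and_count(bound, shapes)
    filtered = apply_threshold(raw, policy)
    table = compute_enrichment(filtered, model, expected_floor=expected_floor,
                               name=name)
    table.policy = policy.describe()
    table.shape_config = shapes.describe() if isinstance(shapes, ShapeConfig) else ""
    return weight_enrichment(table)


# ---------------------------------------------------------------------------
# modified OMP reduction

@dataclass
class OmpResult:
    selected: pd.DataFrame          # rows of the table with omp_weight set
    selected_indices: list[int]     # positions into the candidate list
    residual_trace: list[float]
    probe_description: str = ""


def atom_probe_matrix(patterns: list[MinSeqPattern], probes: list[str],
                      both_strands: bool = True) -> np.ndarray:
    """(n_atoms, n_probes) strand-aware containment indicators.

    A probe contains a pattern when the pattern (or, under both_strands, its
    reverse complement) matches at any offset; gaps match any non-separator
    character.
    """
    joined = "#".join(p.upper() for p in probes)
    starts = np.cumsum([0] + [len(p) + 1 for p in probes[:-1]])
    A = np.zeros((len(patterns), len(probes)), dtype=np.float64)
    for i, pat in enumerate(patterns):
        variants = {pat.text}
        if both_strands:
            variants.add(pat.reverse_complement().text)
        hit = np.zeros(len(probes), dtype=bool)
        for text in variants:
            p = MinSeqPattern.from_text(text)
            rx = re.compile(p.left + "[^#]" * p.gap + p.right)
            for m in rx.finditer(joined):
                j = np.searchsorted(starts, m.start(), side="right") - 1
                if m.end() <= starts[j] + len(probes[j]):
                    hit[j] = True
        A[i] = hit
    return A


def default_probes(bound: ReadSet, max_probes: int = 20000
                   ) -> tuple[list[str], np.ndarray]:
    """Distinct bound reads with read-count frequencies as the OMP target."""
    seqs, counts = np.unique(np.array(list(bound)), return_counts=True)
    order = np.argsort(-counts, kind="mergesort")[:max_probes]
    return list(seqs[order]), counts[order] / bound.total_reads


def omp_reduce(table: MinSeqTable, probes: list[str] | None = None,
               target: np.ndarray | None = None, max_atoms: int = 100,
               tolerance: float = 1e-6, max_candidates: int = 2000,
               bound: ReadSet | None = None) -> OmpResult:
    """Compress the MinSeq set by modified OMP with a nonnegative refit.

    Atoms are strand-aware containment indicator vectors of candidate MinSeqs
    over the probes.  Each iteration greedily selects the atom with the
    highest normalized correlation with the residual, refits all selected
    atoms by nonnegative least squares, and stops at ``max_atoms``, at
    relative residual below ``tolerance``, or when no atom correlates
    positively.  The nonnegative refit guarantees a non-increasing residual.
    """
    if probes is None:
        if bound is None:
            raise ValueError("need probes+target or a bound ReadSet")
        probes, target = default_probes(bound)
    target = np.asarray(target, dtype=np.float64)
    cand = table.top(max_candidates, by="weighted")
    patterns = [MinSeqPattern.from_text(t) for t in cand.pattern]
    A = atom_probe_matrix(patterns, probes).T       # (n_probes, n_atoms)
    norms = np.linalg.norm(A, axis=0)
    usable = norms > 0
    y = target.copy()
    y0 = np.linalg.norm(y)
    selected: list[int] = []
    trace: list[float] = []
    w = np.zeros(0)
    if y0 > 0:
        r = y.copy()
        while len(selected) < min(max_atoms, int(usable.sum())):
            corr = A.T @ r
            score = np.where(usable & (norms > 0), corr / np.maximum(norms, 1e-300),
                             -np.inf)
            score[selected] = -np.inf
            j = int(np.argmax(score))
            if score[j] <= 0:
                break
            selected.append(j)
            w, _ = nnls(A[:, selected], y)
            r = y - A[:, selected] @ w
            trace.append(float(np.linalg.norm(r)))
            if trace[-1] / y0 < tolerance:
                break
    out = cand.iloc[selected].copy()
    out["omp_weight"] = w[:len(selected)] if len(selected) else []
    # write weights back into the parent table
    table.df.loc[out.index, "omp_weight"] = out["omp_weight"]
    return OmpResult(selected=out, selected_indices=selected,
                     residual_trace=trace,
                     probe_description=f"{len(probes)} probes")
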