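"""PAGLO: position-associated inhomogeneous Markov model of the SELEX library.

The model assigns each read position i its own conditional distribution
P(base_i | previous r bases) estimated from library (round 0) reads with an
additive pseudocount.  Expected pattern frequencies are computed by exact
marginalization: a forward pass over the Markov chain that constrains the
pattern's specified positions and sums over every base at gap positions and
at positions outside the pattern window.  This keeps gap probabilities exact
at any model order (a gap is *not* treated as an independent factor).

The model state at position i is the integer code of the last min(i, r)
bases (most significant = oldest), so tables[i] has shape
(4**min(i, r), 4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .patterns import MinSeqPattern
from .seqio import ReadSet

FORMAT_VERSION = 1


@dataclass
class PagloModel:
    order: int
    read_length: int
    tables: list[np.ndarray]  # tables[i]: (4**min(i, order), 4), rows sum to 1
    T: int                    # total library reads used for fitting
    pseudocount: float = 1.0
    _prefix: list[np.ndarray] = field(default_factory=list, repr=False)
    _transfer: list[np.ndarray] = field(default_factory=list, repr=False)

    # -- construction ------------------------------------------------------

    def __post_init__(self):
        for i, t in enumerate(self.tables):
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"conditional rows at position {i} do not sum to 1")

    def _state_size(self, i: int) -> int:
        return 4 ** min(i, self.order)

    def _ensure_caches(self):
        """Unconstrained transfer matrices and prefix state distributions."""
        if self._transfer:
            return
        L, r = self.read_length, self.order
        transfer = []
        for i in range(L):
            S, S1 = self._state_size(i), self._state_size(i + 1)
            G = np.zeros((S, S1))
            for s in range(S):
                for b in range(4):
                    s1 = s * 4 + b if S1 == S * 4 else (s % max(S // 4, 1)) * 4 + b
                    if r == 0:
                        s1 = 0
                    G[s, s1] += self.tables[i][s, b]
            transfer.append(G)
        prefix = [np.ones(1)]
        for i in range(L):
            prefix.append(prefix[-1] @ transfer[i])
        self._transfer = transfer
        self._prefix = prefix

    # -- probabilities -----------------------------------------------------

    def masked_probability_batch(self, positions: np.ndarray, base_matrix: np.ndarray,
                                 offset: int) -> np.ndarray:
        """P(read matches bases at ``offset + positions``) for many base rows.

        ``positions`` are relative specified positions (sorted); ``base_matrix``
        is (P, len(positions)) with codes 0..3.  Unlisted positions inside the
        window are gaps (marginalized exactly); positions outside the window
        marginalize to 1.
        """
        self._ensure_caches()
        positions = np.asarray(positions, dtype=np.intp)
        base_matrix = np.atleast_2d(np.asarray(base_matrix, dtype=np.intp))
        span = int(positions.max()) + 1 if positions.size else 0
        if offset < 0 or offset + span > self.read_length:
            raise ValueError(f"offset {offset} puts span {span} outside read "
                             f"length {self.read_length}")
        P = base_matrix.shape[0]
        spec = {int(p): j for j, p in enumerate(positions)}
        f = np.tile(self._prefix[offset], (P, 1))
        for i in range(offset, offset + span):
            A = self.tables[i]
            S, S1 = self._state_size(i), self._state_size(i + 1)
            j = spec.get(i - offset)
            if j is None:
                f = f @ self._transfer[i]
                continue
            bases = base_matrix[:, j]
            w = A[:, bases].T                      # (P, S)
            g = f * w
            if self.order == 0:
                f = g
            elif S1 == S * 4:                      # state still growing (i < r)
                cols = np.arange(S)[None, :] * 4 + bases[:, None]
                f = np.zeros((P, S1))
                np.put_along_axis(f, cols, g, axis=1)
            else:                                  # steady state: drop oldest base
                summed = g.reshape(P, 4, S // 4).sum(axis=1)
                cols = np.arange(S // 4)[None, :] * 4 + bases[:, None]
                f = np.zeros((P, S1))
                np.put_along_axis(f, cols, summed, axis=1)
        return f.sum(axis=1)

    def pattern_probability(self, pattern: MinSeqPattern, offset: int) -> float:
        """Probability that a model read matches ``pattern`` at ``offset``."""
        p = self.masked_probability_batch(pattern.spec_positions,
                                          pattern.spec_bases[None, :], offset)
        return float(p[0])

    def pattern_offsets(self, pattern: MinSeqPattern) -> np.ndarray:
        n = self.read_length - pattern.span + 1
        if n <= 0:
            raise ValueError(f"pattern span {pattern.span} exceeds read length")
        return np.arange(n)

    def expected_count(self, pattern: MinSeqPattern,
                       ) -> tuple[float, np.ndarray]:
        """C*(x) = T * sum over offsets of the match probability.

        Returns the expected count and the per-offset probability breakdown.
        """
        probs = np.array([self.pattern_probability(pattern, o)
                          for o in self.pattern_offsets(pattern)])
        return float(self.T * probs.sum()), probs

    def expected_counts_batch(self, shape: tuple[int, int, int],
                              codes: np.ndarray) -> np.ndarray:
        """Vectorized C*(x) for many same-shape patterns given as base-4 codes."""
        k, g, l = shape
        n = k + l
        codes = np.asarray(codes, dtype=np.int64)
        shifts = np.arange(n - 1, -1, -1) * 2
        bm = (codes[:, None] >> shifts[None, :]) & 3
        positions = np.array(list(range(k)) + list(range(k + g, k + g + l)), dtype=np.intp)
        span = k + g + l
        total = np.zeros(len(codes))
        for o in range(self.read_length - span + 1):
            total += self.masked_probability_batch(positions, bm, o)
        return self.T * total

    def position_marginals(self) -> np.ndarray:
        """(L, 4) marginal base probabilities under the model."""
        out = np.empty((self.read_length, 4))
        for i in range(self.read_length):
            out[i] = self.masked_probability_batch(
                np.array([0]), np.arange(4)[:, None], i)
        return out

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "format": "paglo", "version": FORMAT_VERSION,
            "order": self.order, "read_length": self.read_length,
            "T": self.T, "pseudocount": self.pseudocount,
            "tables": [t.tolist() for t in self.tables],
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path) -> "PagloModel":
        obj = json.loads(Path(path).read_text())
        if obj.get("format") != "paglo":
            raise ValueError(f"{path} is not a PAGLO model file")
        return cls(order=obj["order"], read_length=obj["read_length"],
                   tables=[np.array(t) for t in obj["tables"]],
                   T=obj["T"], pseudocount=obj["pseudocount"])


def fit_paglo(library: ReadSet, order: int = 1, pseudocount: float = 1.0) -> PagloModel:
    """Fit the position-associated Markov model on library (round 0) reads.

    Reads containing ambiguous bases are excluded from the frequency counts
    but still contribute to the recorded total T.
    """
    if len(library) == 0:
        raise ValueError("cannot fit PAGLO on an empty library")
    L = library.read_length
    if order >= L:
        raise ValueError(f"order {order} must be < read length {L}")
    if order < 0:
        raise ValueError("order must be >= 0")
    arr, valid = library.encoded()
    arr = arr[valid].astype(np.int64)
    if arr.shape[0] == 0:
        raise ValueError("no unambiguous reads to fit on")
    tables = []
    for i in range(L):
        r_i = min(i, order)
        S = 4 ** r_i
        if r_i == 0:
            ctx = np.zeros(arr.shape[0], dtype=np.int64)
        else:
            ctx = np.zeros(arr.shape[0], dtype=np.int64)
            for j in range(i - r_i, i):
                ctx = ctx * 4 + arr[:, j]
        counts = np.bincount(ctx * 4 + arr[:, i], minlength=S * 4).reshape(S, 4)
        probs = counts + pseudocount
        denom = probs.sum(axis=1, keepdims=True)
        if pseudocount == 0:
            denom = np.where(denom == 0, 1, denom)  # unseen context -> zeros row
            probs = probs / denom
            probs[counts.sum(axis=1) == 0] = 0.25   # fall back to uniform
        else:
            probs = probs / denom
        tables.append(probs)
    return PagloModel(order=order, read_length=L, tables=tables,
                      T=library.total_reads, pseudocount=pseudocount)
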