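"""Pairwise similarity of DNA-protein interactomes and clustergram ordering.

For each pair of MinSeq tables the union of the two top-n (OMP-chosen when
available) pattern sets is taken; each side contributes its enrichment for
every union pattern, falling back — for patterns absent from a table — to
scoring the pattern's concrete sequence (gaps as N wildcards) against that
table's full MinSeq model, exactly as peak scoring would.  Pearson's r over
the two vectors measures interactome similarity; hierarchical clustering of
the correlation rows (Euclidean distance) orders the clustergram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .annotate import ScoringModel, score_sequence
from .minseq import MinSeqTable
from .patterns import MinSeqPattern


@dataclass
class ProfileMatrix:
    """Symmetric Pearson-r matrix over samples with unit diagonal."""

    r: pd.DataFrame
    top_n: int

    @property
    def labels(self) -> list[str]:
        return list(self.r.index)

    def to_tsv(self, path) -> None:
        self.r.to_csv(path, sep="\t")


def _profile_value(table: MinSeqTable, model: ScoringModel,
                   lookup: dict[str, float], pattern: str) -> float:
    """Enrichment of a pattern under one table: direct if recorded, else the
    model score of the pattern's concrete sequence."""
    if pattern in lookup:
        return lookup[pattern]
    return score_sequence(model, MinSeqPattern.from_text(pattern).concrete())


def pairwise_profile_correlation(tables: dict[str, MinSeqTable],
                                 top_n: int = 100) -> ProfileMatrix:
    """Pearson correlation of every pair of interactomes over the union of
    their top-n MinSeqs."""
    if len(tables) < 2:
        raise ValueError("need at least two tables to compare")
    names = list(tables)
    tops = {n: list(tables[n].top(top_n).pattern) for n in names}
    lookups = {n: dict(zip(tables[n].df.pattern, tables[n].df.enrichment))
               for n in names}
    models = {n: ScoringModel.from_table(tables[n]) for n in names}
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            union = sorted(set(tops[a]) | set(tops[b]))
            va = np.array([_profile_value(tables[a], models[a], lookups[a], p)
                           for p in union])
            vb = np.array([_profile_value(tables[b], models[b], lookups[b], p)
                           for p in union])
            if va.std() == 0 or vb.std() == 0:
                rv = 0.0
            else:
                rv = float(np.corrcoef(va, vb)[0, 1])
            r.loc[a, b] = r.loc[b, a] = rv
    return ProfileMatrix(r=r, top_n=top_n)


def hierarchical_order(matrix: ProfileMatrix, linkage: str = "complete"
                       ) -> tuple[list[str], np.ndarray]:
    """Agglomerative clustering of correlation rows with Euclidean distance.

    Returns (leaf order, scipy linkage matrix).  Rows are clustered on their
    full correlation profiles, so identical profiles merge first; the leaf
    order is deterministic for a fixed input.
    """
    if linkage not in ("complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    rows = matrix.r.to_numpy()
    d = np.sqrt(np.maximum(
        ((rows[:, None, :] - rows[None, :, :]) ** 2).sum(axis=2), 0.0))
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    leaves = hierarchy.leaves_list(Z)
    return [matrix.labels[i] for i in leaves], Z


def merge_tree_newick(matrix: ProfileMatrix, Z: np.ndarray) -> str:
    """Render the merge tree as a Newick string with merge heights."""
    labels = matrix.labels
    n = len(labels)
    nodes: dict[int, tuple[str, float]] = {i: (labels[i], 0.0) for i in range(n)}
    for i, (a, b, h, _cnt) in enumerate(Z):
        (ta, ha), (tb, hb) = nodes[int(a)], nodes[int(b)]
        nodes[n + i] = (f"({ta}:{h - ha:.6g},{tb}:{h - hb:.6g})", float(h))
    return nodes[n + len(Z) - 1][0] + ";"
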