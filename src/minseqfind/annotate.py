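"""Peak Assign and SNP Align: scoring genomic sequence with a MinSeq model.

Peak Assign scores ChIP-derived intervals with a MinSeq set, builds ROC
curves against base-permuted negatives (two permutations per peak by
default), summarizes with AUROC, and assigns each peak an S score — the
maximum over detection thresholds of TPR / (TPR + FPR), ranging from 1
(detected at zero false-positive rate) down to 0.5 (no better than the
permuted background).  Binding-mode heatmaps decompose a model into
monomer / DR / IR / ER half-site arrangements with 0-8 nt spacers
(28 categories).

SNP Align compares the MinSeq score of the reference-allele and
alternate-allele flank windows:  log2((E_alt + eta) / (E_ref + eta)) with
eta = min(10, 10% of the model's maximum enrichment); |log2FC| >= 1 calls a
binding-site gain or loss.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .patterns import IUPAC, MinSeqPattern, iupac_match, revcomp
from .seqio import GenomicInterval, SnpRecord

ARRANGEMENTS = ("DR", "IR", "ER")
MAX_SPACER = 8


# ---------------------------------------------------------------------------
# scoring

@dataclass
class ScoringModel:
    """A MinSeq set with enrichments, compiled for sequence scoring."""

    patterns: list[MinSeqPattern]
    enrichments: np.ndarray
    window_agg: str = "max"        # {max, sum}
    strand_policy: str = "both"    # {given, both}
    no_match_score: float = 0.0
    _compiled: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.enrichments = np.asarray(self.enrichments, dtype=float)
        if len(self.patterns) == 0:
            raise ValueError("scoring model needs at least one record")
        if (self.enrichments < 0).any():
            raise ValueError("enrichments must be >= 0")
        if self.window_agg not in ("max", "sum"):
            raise ValueError(f"unknown window_agg {self.window_agg!r}")
        if self.strand_policy not in ("given", "both"):
            raise ValueError(f"unknown strand_policy {self.strand_policy!r}")

    @classmethod
    def from_table(cls, table, top_n: int | None = None, **kw) -> "ScoringModel":
        df = table.top(top_n) if top_n else table.ranked()
        return cls([MinSeqPattern.from_text(t) for t in df.pattern],
                   df.enrichment.to_numpy(), **kw)

    @property
    def max_enrichment(self) -> float:
        return float(self.enrichments.max())

    @property
    def max_span(self) -> int:
        return max(p.span for p in self.patterns)

    def _regexes(self):
        """Per-record compiled regexes (plus reverse-complement variants)."""
        if not self._compiled:
            for pat in self.patterns:
                variants = [pat]
                if self.strand_policy == "both":
                    rc = pat.reverse_complement()
                    if rc.text != pat.text:
                        variants.append(rc)
                # gaps span anything (incl. N); specified bases are ACGT-only
                self._compiled.append(
                    [re.compile(f"(?=({v.left}.{{{v.gap}}}{v.right}))")
                     for v in variants])
        return self._compiled

    def matches(self, seq: str) -> list[tuple[int, int, float]]:
        """All (start, end, enrichment) pattern matches in ``seq``."""
        seq = seq.upper()
        out = []
        for (pat, rxs, e) in zip(self.patterns, self._regexes(), self.enrichments):
            for rx in rxs:
                for m in rx.finditer(seq):
                    out.append((m.start(), m.start() + pat.span, float(e)))
        return out


def score_sequence(model: ScoringModel, seq: str) -> float:
    """Slide windows of the model's max span over ``seq``; the window score
    aggregates (max or sum) the enrichments of MinSeqs contained in the
    window; the sequence score is the max over windows."""
    if len(seq) < 1:
        raise ValueError("empty sequence")
    hits = model.matches(seq)
    if not hits:
        return model.no_match_score
    if model.window_agg == "max":
        return max(e for _, _, e in hits)
    n = min(model.max_span, len(seq))
    best = model.no_match_score
    for w in range(len(seq) - n + 1):
        s = sum(e for a, b, e in hits if a >= w and b <= w + n)
        best = max(best, s)
    return best


def score_sequences(model: ScoringModel, seqs) -> np.ndarray:
    return np.array([score_sequence(model, s) for s in seqs])


# ---------------------------------------------------------------------------
# negatives + ROC

def make_negatives(seq: str, n_perm: int = 2,
                   rng: np.random.Generator | None = None,
                   dinucleotide: bool = False) -> list[str]:
    """Random base permutations of ``seq`` (known negatives).

    The default permutes single bases, preserving base composition; the
    dinucleotide option shuffles non-overlapping dinucleotide blocks instead.
    """
    rng = np.random.default_rng() if rng is None else rng
    out = []
    for _ in range(n_perm):
        if dinucleotide:
            blocks = [seq[i:i + 2] for i in range(0, len(seq), 2)]
            out.append("".join(np.array(blocks)[rng.permutation(len(blocks))]))
        else:
            out.append("".join(np.array(list(seq))[rng.permutation(len(seq))]))
    return out


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float


def roc(scores_pos, scores_neg) -> RocCurve:
    """ROC over all distinct thresholds; AUROC by trapezoid with midrank ties.

    AUROC = 1 is complete separation of peaks from permuted negatives;
    0.5 is chance.
    """
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("need scores for both classes")
    y = np.r_[np.ones(scores_pos.size), np.zeros(scores_neg.size)]
    s = np.r_[scores_pos, scores_neg]
    fpr, tpr, thr = roc_curve(y, s)
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr,
                    auroc=float(roc_auc_score(y, s)))


def s_scores(scores_pos, scores_neg) -> np.ndarray:
    """Per-positive S = max over thresholds at which the peak is detected of
    TPR / (TPR + FPR), in [0.5, 1]."""
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    values = np.unique(np.r_[scores_pos, scores_neg])
    # candidate thresholds: just below each distinct value, detection is ">"
    cand = np.r_[values - 1e-12 * np.maximum(1.0, np.abs(values)),
                 values.min() - 1.0]
    tpr = (scores_pos[None, :] > cand[:, None]).mean(axis=1)
    fpr = (scores_neg[None, :] > cand[:, None]).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(tpr + fpr > 0, tpr / (tpr + fpr), 0.0)
    out = np.empty(scores_pos.size)
    for i, s in enumerate(scores_pos):
        detected = s > cand
        out[i] = ratio[detected].max() if detected.any() else 0.5
    return out


@dataclass
class PeakScore:
    interval: GenomicInterval
    score: float
    s_score: float
    per_mode_precision: dict = field(default_factory=dict)


def peak_s_scores(model: ScoringModel, peaks: list[GenomicInterval],
                  n_perm: int = 2, rng: np.random.Generator | None = None,
                  ) -> tuple[list[PeakScore], RocCurve]:
    """Score peaks and their permuted negatives; per-peak S plus the ROC."""
    rng = np.random.default_rng() if rng is None else rng
    pos = [p.sequence for p in peaks]
    neg = [n for p in pos for n in make_negatives(p, n_perm, rng)]
    sp = score_sequences(model, pos)
    sn = score_sequences(model, neg)
    curve = roc(sp, sn)
    ss = s_scores(sp, sn)
    return ([PeakScore(iv, float(s), float(t))
             for iv, s, t in zip(peaks, sp, ss)], curve)


# ---------------------------------------------------------------------------
# binding-mode taxonomy

@dataclass(frozen=True)
class ModeCategory:
    arrangement: str            # monomer | DR | IR | ER
    spacer: int | None = None   # absent for monomer
    half_site: str = ""

    @property
    def label(self) -> str:
        if self.arrangement == "monomer":
            return "monomer"
        return f"{self.arrangement}{self.spacer}"


def mode_categories(half_site: str) -> list[ModeCategory]:
    """The 28 half-site arrangement categories: monomer + {DR, IR, ER} x 0-8."""
    cats = [ModeCategory("monomer", None, half_site)]
    for arr in ARRANGEMENTS:
        for n in range(MAX_SPACER + 1):
            cats.append(ModeCategory(arr, n, half_site))
    return cats


def _matches_category(pattern: MinSeqPattern, cat: ModeCategory) -> bool:
    h = cat.half_site
    hl = len(h)
    rc_h = revcomp(h)
    if cat.arrangement == "monomer":
        if pattern.l != 0 or pattern.k != hl:
            return False
        return iupac_match(h, pattern.left) or iupac_match(rc_h, pattern.left)
    if pattern.k != hl or pattern.l != hl or pattern.gap != cat.spacer:
        return False
    pairs = {"DR": [(h, h), (rc_h, rc_h)],          # minus-strand DR reads as rc/rc
             "IR": [(h, rc_h)],
             "ER": [(rc_h, h)]}[cat.arrangement]
    return any(iupac_match(a, pattern.left) and iupac_match(b, pattern.right)
               for a, b in pairs)


def classify_modes(model: ScoringModel, half_site: str
                   ) -> tuple[dict[str, ScoringModel | None], pd.Series]:
    """Partition a MinSeq model into the 28 binding-mode categories.

    Every record lands in exactly one category (or "other"); precedence when
    several match is monomer, then DR, IR, ER with smaller spacers first.
    Returns (label -> sub-model or None, per-category summed enrichment).
    """
    for c in half_site.upper():
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC code {c!r} in half site")
    cats = mode_categories(half_site.upper())
    bins: dict[str, list[int]] = {c.label: [] for c in cats}
    bins["other"] = []
    for i, pat in enumerate(model.patterns):
        for cat in cats:
            if _matches_category(pat, cat):
                bins[cat.label].append(i)
                break
        else:
            bins["other"].append(i)
    sub_models = {}
    totals = {}
    for label, idx in bins.items():
        totals[label] = float(model.enrichments[idx].sum()) if idx else 0.0
        sub_models[label] = None if not idx else ScoringModel(
            [model.patterns[i] for i in idx], model.enrichments[idx],
            window_agg=model.window_agg, strand_policy=model.strand_policy,
            no_match_score=model.no_match_score)
    return sub_models, pd.Series(totals)


def mode_precision_matrix(model: ScoringModel, peaks: list[GenomicInterval],
                          half_site: str, n_perm: int = 2,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Peaks x 28-category matrix of per-peak S (normalized precision).

    Each category's sub-model scores all peaks against the global permuted
    negative pool; categories with no matching record give NaN columns so
    they drop out of heatmaps.
    """
    rng = np.random.default_rng() if rng is None else rng
    sub_models, _ = classify_modes(model, half_site)
    pos = [p.sequence for p in peaks]
    negs = [n for p in pos for n in make_negatives(p, n_perm, rng)]
    data = {}
    for label, sub in sub_models.items():
        if label == "other":
            continue
        if sub is None:
            data[label] = np.full(len(peaks), np.nan)
        else:
            data[label] = s_scores(score_sequences(sub, pos),
                                   score_sequences(sub, negs))
    names = [p.name or f"{p.chrom}:{p.start}-{p.end}" for p in peaks]
    return pd.DataFrame(data, index=names)


# ---------------------------------------------------------------------------
# SNP Align

@dataclass
class SnpScore:
    snp: SnpRecord
    e_ref: float
    e_alt: float
    eta: float
    log2fc: float
    call: str                  # gain | loss | neutral


def snp_eta(model: ScoringModel) -> float:
    """Regularizer: the lesser of absolute enrichment 10 and 10% of the max."""
    return min(10.0, 0.1 * model.max_enrichment)


def snp_logfc(model: ScoringModel, snp: SnpRecord,
              fold_threshold: float = 2.0) -> SnpScore:
    """Allelic binding change: log2((E_alt + eta) / (E_ref + eta))."""
    e_ref = score_sequence(model, snp.ref_flank)
    e_alt = score_sequence(model, snp.alt_flank)
    eta = snp_eta(model)
    lfc = float(np.log2((e_alt + eta) / (e_ref + eta)))
    cut = np.log2(fold_threshold)
    call = "gain" if lfc >= cut else "loss" if lfc <= -cut else "neutral"
    return SnpScore(snp, e_ref, e_alt, eta, lfc, call)


def snp_table(model: ScoringModel, snps: list[SnpRecord]) -> pd.DataFrame:
    rows = []
    for snp in snps:
        s = snp_logfc(model, snp)
        rows.append({"id": snp.id, "chrom": snp.chrom, "pos": snp.pos,
                     "ref": snp.ref_allele, "alt": snp.alt_allele,
                     "e_ref": s.e_ref, "e_alt": s.e_alt, "eta": s.eta,
                     "log2fc": s.log2fc, "call": s.call})
    return pd.DataFrame(rows)
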