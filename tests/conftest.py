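import numpy as np
import pytest

import minseqfind as mf


@pytest.fixture(scope="session")
def uniform_library():
    """A plant-free 20k-read library with uniform composition."""
    return mf.simulate_library(mf.SimConfig(library_size=20_000, planted=[], seed=42))


@pytest.fixture(scope="session")
def uniform_model(uniform_library):
    return mf.fit_paglo(uniform_library, order=1)


@pytest.fixture(scope="session")
def biased_short_model():
    """Order-1 model on 6-nt reads with a skewed composition (for oracles)."""
    rng = np.random.default_rng(7)
    reads = ["".join(rng.choice(list("ACGT"), p=[0.4, 0.25, 0.1, 0.25], size=6))
             for _ in range(4000)]
    return mf.fit_paglo(mf.ReadSet(reads), order=1, pseudocount=1.0)


@pytest.fixture()
def tiny_genome(tmp_path):
    """A two-chromosome FASTA small enough to slice by hand."""
    path = tmp_path / "genome.fa"
    path.write_text(">chr1\nACGTACGT\n>chr2\n" + "ACGTTGCA" * 8 + "\n")
    return path


def make_scoring_model(pairs, **kw):
    """pairs: [(pattern text, enrichment), ...]"""
    pats = [mf.MinSeqPattern.from_text(t) for t, _ in pairs]
    return mf.ScoringModel(pats, np.array([e for _, e in pairs]), **kw)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
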