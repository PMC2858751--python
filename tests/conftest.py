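"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the library's vectorized/recursive code
paths: correlations go through scipy or explicit loops, the motif matcher is
a plain recursive enumerator over gap lengths and repeat counts, and the
null models enumerate all pairs with itertools.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from utrx import ExpressionMatrix, GenomicInterval, ProbeSet, Transcript
from utrx.motifs import Gap, MotifPattern, Repeat, Word
from utrx.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_bundle():
    """The default study-condition bundle: 200 genes, 70 samples, planted r=0.9."""
    cfg = SyntheticConfig(n_genes=200, rng_seed=0)
    bundle, truth = generate_dataset(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def small_bundle():
    cfg = SyntheticConfig(n_genes=40, rng_seed=7)
    bundle, truth = generate_dataset(cfg)
    return cfg, bundle, truth


def make_matrix(rows: dict[str, list[float]], tissues=None) -> ExpressionMatrix:
    n = len(next(iter(rows.values())))
    samples = [f"s{i}" for i in range(n)]
    return ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=samples), tissues
    )


def iv(chrom, start, end, strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def ps(pid, *intervals):
    return ProbeSet(pid, tuple(intervals))


def tr(tid, symbol, chrom, start, end, strand="+"):
    return Transcript(id=tid, gene_symbol=symbol,
                      span=GenomicInterval(chrom, start, end, strand))


# --- oracle: all-pairs Pearson tail via scipy ------------------------------

def brute_force_pair_fpr(values: np.ndarray, cutoff: float) -> tuple[float, int]:
    """Fraction of all unordered row pairs with scipy Pearson r > cutoff."""
    n_above = 0
    pairs = list(itertools.combinations(range(values.shape[0]), 2))
    for i, j in pairs:
        r, _ = stats.pearsonr(values[i], values[j])
        n_above += r > cutoff
    return n_above / len(pairs), len(pairs)


# --- oracle: naive motif matcher -------------------------------------------

def naive_match(s: str, pos: int, elems) -> bool:
    """Explicit enumeration of gap lengths, repeat counts and word variants."""
    if not elems:
        return True
    e, rest = elems[0], elems[1:]
    if isinstance(e, Gap):
        return any(
            pos + g <= len(s) and naive_match(s, pos + g, rest)
            for g in range(e.min, e.max + 1)
        )
    if isinstance(e, Repeat):
        for c in range(e.min, e.max + 1):
            seg = s[pos : pos + c]
            if len(seg) < c or any(ch not in e.allowed for ch in seg):
                break
            if naive_match(s, pos + c, rest):
                return True
        return False
    assert isinstance(e, Word)
    s_max, i_max, d_max = e.mismatch
    assert i_max == 0 and d_max == 0, "oracle covers substitution-only words"
    for variant in e.variants:
        end = pos + len(variant)
        if end > len(s):
            continue
        mism = sum(s[pos + k] not in variant[k] for k in range(len(variant)))
        if mism <= s_max and naive_match(s, end, rest):
            return True
    return False


def naive_scan_starts(seq: str, pattern: MotifPattern) -> list[int]:
    s = seq.upper().replace("U", "T")
    return [p for p in range(len(s)) if naive_match(s, p, pattern.elements)]
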