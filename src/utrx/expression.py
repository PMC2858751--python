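"""Expression filtering, Pearson screening and the two false-positive nulls.

All expression values are log2 signals (the matrix is expected to come out of
an RMA-style normalization).  Two empirical null constructions estimate the
false-positive rate of the correlation screen:

random-pair null
    Pearson r between randomly drawn above-noise probe-set pairs; the tail
    fraction above the cutoff estimates the dataset-wide false-positive rate.

cross-chromosome null
    for one probe set, the fraction of uniquely-mapping probe sets on *other*
    chromosomes that exceed the cutoff — under the (stringent) assumption
    that a transcript never spans two chromosomes, every such correlation is
    a false positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, UndefinedCorrelationError, ValidationError

logger = logging.getLogger("utrx")


class ExpressionMatrix:
    """log2 signals, probe sets (rows) × samples (columns), with tissue labels.

    Wraps a :class:`pandas.DataFrame`; values must be finite, row ids unique,
    and there must be at least two samples.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        tissues: Optional[Mapping[str, str]] = None,
    ):
        if values.shape[1] < 2:
            raise ValidationError("expression matrix needs at least 2 samples")
        if not values.index.is_unique:
            dup = values.index[values.index.duplicated()][:10].tolist()
            raise ValidationError(f"duplicate probe-set ids: {dup}")
        if not values.columns.is_unique:
            raise ValidationError("duplicate sample ids")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        self.values = values.astype(float)
        self.values.index.name = "probe_set_id"
        self.values.columns.name = None
        if tissues is not None:
            missing = [s for s in values.columns if s not in tissues]
            if missing:
                raise ValidationError(
                    f"samples without tissue label: {missing[:10]}"
                )
            self.tissues = {s: tissues[s] for s in values.columns}
        else:
            self.tissues = None

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.values.index

    def row(self, probe_id: str) -> np.ndarray:
        return self.values.loc[probe_id].to_numpy(dtype=float)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation of two equal-length vectors.

    Raises :class:`UndefinedCorrelationError` when either vector has zero
    variance — a pair with a flat profile is excluded upstream, never
    silently scored 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("pearson expects two 1-d vectors of equal length")
    if xa.size < 2:
        raise ValidationError("pearson needs at least 2 observations")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero-variance profile")
    r = float(xc @ yc) / (sx * sy)
    return max(-1.0, min(1.0, r))


def above_noise(row: Sequence[float], threshold: float) -> bool:
    """True iff the profile strictly exceeds ``threshold`` in at least one array."""
    arr = np.asarray(row, dtype=float)
    if arr.size == 0:
        return False
    return bool(arr.max() > threshold)


@dataclass(frozen=True)
class NullEstimate:
    """A false-positive-rate estimate from one of the two null constructions."""

    method: str  # "random_pair" | "cross_chromosome"
    cutoff: float
    fpr: float
    n_comparisons: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.fpr <= 1.0):
            raise ValidationError(f"fpr {self.fpr} outside [0, 1]")
        if self.n_comparisons <= 0:
            raise ValidationError("n_comparisons must be positive")


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; returns (Z, nonzero-variance mask).

    For standardized rows r = z_i . z_j, which vectorizes the pair screen.
    """
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    ok = norms > 0
    z = np.zeros_like(centered)
    z[ok] = centered[ok] / norms[ok, None]
    return z, ok


def _eligible_rows(
    m: ExpressionMatrix,
    *,
    threshold: Optional[float],
) -> tuple[list[str], np.ndarray]:
    """Row ids passing the noise filter (if any) and with nonzero variance."""
    values = m.values.to_numpy(dtype=float)
    ids = np.asarray(m.probe_ids, dtype=object)
    keep = np.ones(len(ids), dtype=bool)
    if threshold is not None:
        keep &= values.max(axis=1) > threshold
    var_ok = values.std(axis=1) > 0
    n_flat = int((keep & ~var_ok).sum())
    if n_flat:
        logger.info("excluding %d zero-variance rows from the null", n_flat)
    keep &= var_ok
    return list(ids[keep]), values[keep]


def random_pair_null(
    m: ExpressionMatrix,
    n_pairs: int,
    cutoff: float,
    seed: int,
    *,
    threshold: Optional[float] = 6.0,
    exhaustive: bool = False,
) -> NullEstimate:
    """Tail of the Pearson distribution over random above-noise probe-set pairs.

    Draws ``n_pairs`` unordered row pairs uniformly (a row never pairs with
    itself; distinct draws may repeat a pair) from rows passing the noise
    filter, and reports the fraction with r > ``cutoff``.  With
    ``exhaustive=True`` every unordered pair is enumerated exactly once
    instead, which is the brute-force reference on small matrices.
    """
    ids, values = _eligible_rows(m, threshold=threshold)
    k = len(ids)
    if k < 2:
        raise ComputationError(
            f"random-pair null needs >= 2 eligible rows, found {k}"
        )
    z, _ = _standardize_rows(values)
    if exhaustive:
        rmat = z @ z.T
        iu = np.triu_indices(k, 1)
        rs = rmat[iu]
        n_comparisons = rs.size
    else:
        if n_pairs <= 0:
            raise ValidationError("n_pairs must be positive")
        rng = np.random.default_rng(seed)
        a = rng.integers(0, k, size=n_pairs)
        b = rng.integers(0, k - 1, size=n_pairs)
        b = b + (b >= a)  # uniform over the k-1 partners of a
        rs = np.einsum("ij,ij->i", z[a], z[b])
        n_comparisons = n_pairs
    fpr = float(np.mean(rs > cutoff))
    return NullEstimate("random_pair", cutoff, fpr, int(n_comparisons))


def cross_chromosome_fpr(
    p: str,
    m: ExpressionMatrix,
    locations: Mapping[str, str],
    cutoff: float,
    *,
    threshold: Optional[float] = None,
) -> NullEstimate:
    """Per-probe-set false-positive rate from other-chromosome correlations.

    ``locations`` maps probe-set id → chromosome and should contain only
    uniquely-mapping probe sets; every id in it that is present in the matrix
    and sits on a different chromosome than ``p`` is correlated against
    ``p``'s profile exhaustively.  By default no noise filter is applied to
    the comparison rows (eligibility is a config switch).
    """
    if p not in m:
        raise ValidationError(f"probe set {p!r} missing from expression matrix")
    if p not in locations:
        raise ValidationError(f"probe set {p!r} missing from locations map")
    own_chrom = locations[p]
    ids, values = _eligible_rows(m, threshold=threshold)
    index = {pid: i for i, pid in enumerate(ids)}
    other_idx = [
        index[pid]
        for pid in ids
        if pid != p and pid in locations and locations[pid] != own_chrom
    ]
    if not other_idx:
        raise ComputationError(
            f"no eligible comparison rows for {p!r} on other chromosomes"
        )
    row = m.row(p)
    rc = row - row.mean()
    norm = math.sqrt(float(rc @ rc))
    if norm == 0.0:
        raise UndefinedCorrelationError(f"probe set {p!r} has zero variance")
    z, _ = _standardize_rows(values)
    rs = z[other_idx] @ (rc / norm)
    fpr = float(np.mean(rs > cutoff))
    return NullEstimate("cross_chromosome", cutoff, fpr, len(other_idx))


def expected_false_positives(n_predictions: int, fpr: float) -> int:
    """Expected number of false positives among ``n_predictions`` calls.

    floor(n * fpr): 845 predictions at the 1.84% cross-chromosome rate gives
    15 and at the 2.18% random-pair tail gives 18.
    """
    if not (0.0 <= fpr <= 1.0):
        raise ValidationError(f"fpr {fpr} outside [0, 1]")
    if n_predictions < 0:
        raise ValidationError("n_predictions must be non-negative")
    return int(math.floor(n_predictions * fpr))
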