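"""Extension regions, conservation scoring and 3'-end tag confirmation.

The predicted extension region runs from the annotated transcript 3' end to
the far (3'-most) edge of the extended probe set's target, in transcript
orientation.  Conservation is compared against matched random sets drawn from
a known-3'UTR pool and an intergenic pool: for each of ``n_sets`` random sets
with the same per-region lengths as the predictions, a bp-weighted mean
phastCons-style score is computed, and the prediction mean is expressed as a
normal Z-statistic against the intergenic set means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .errors import ComputationError, ValidationError
from .intervals import GenomicInterval, three_prime_coordinate
from .annotation import Transcript

_TINY_P = 5e-324  # smallest positive float; keeps p in (0, 1] when sf underflows


@dataclass(frozen=True)
class ExtensionRegion:
    """The genomic region a predicted 3'UTR extension covers."""

    prediction_id: str
    region: GenomicInterval

    @property
    def length(self) -> int:
        return self.region.length


def pair_distance(
    primary_target: GenomicInterval, extended_target: GenomicInterval
) -> int:
    """Gap (bp) between the facing edges of a primary/extended target pair.

    Measured in transcript orientation, from the primary target's 3'
    coordinate to the extended target's 5'-most coordinate.  Raises for
    overlapping targets; abutting targets give 0 (pairing upstream already
    rejects them).
    """
    if (
        primary_target.chrom != extended_target.chrom
        or primary_target.strand != extended_target.strand
    ):
        raise ValidationError("pair members must share chromosome and strand")
    if primary_target.strand == "+":
        gap = extended_target.start - primary_target.end
    else:
        gap = primary_target.start - extended_target.end
    if gap < 0:
        raise ValidationError(
            f"extended target {extended_target} is not downstream of {primary_target}"
        )
    return gap


def extension_region(
    t: Transcript,
    extended_target: GenomicInterval,
    *,
    span_mode: str = "far",
) -> ExtensionRegion:
    """Region from the annotated 3' end of ``t`` to the extended target.

    ``span_mode="far"`` (default) ends at the target's 3'-most edge, so the
    region includes the inter-probe gap plus the probe target itself;
    ``"near"`` stops at the target's proximal edge.
    """
    if span_mode not in ("far", "near"):
        raise ValidationError(f"unknown span_mode {span_mode!r}")
    if (
        extended_target.chrom != t.span.chrom
        or extended_target.strand != t.span.strand
    ):
        raise ValidationError("extended target must share the transcript's locus")
    strand = t.span.strand
    t3 = t.three_prime
    if strand == "+":
        if extended_target.start < t3:
            raise ValidationError(
                f"target {extended_target} overlaps the transcript span of {t.id}"
            )
        end = extended_target.end if span_mode == "far" else extended_target.start
        if end <= t3:
            raise ValidationError("degenerate extension region")
        region = GenomicInterval(t.span.chrom, t3, end, strand)
    else:
        if extended_target.end > t3:
            raise ValidationError(
                f"target {extended_target} overlaps the transcript span of {t.id}"
            )
        start = extended_target.start if span_mode == "far" else extended_target.end
        if start >= t3:
            raise ValidationError("degenerate extension region")
        region = GenomicInterval(t.span.chrom, start, t3, strand)
    return ExtensionRegion(prediction_id=t.id, region=region)


class ConservationTrack:
    """Per-base scores in [0, 1], stored as sorted non-overlapping runs.

    Bases absent from the track score 0 — phastCons emits no value for
    unalignable bases, and treating absence as non-conservation is the
    conservative choice.
    """

    def __init__(self, runs_by_chrom):
        """``runs_by_chrom``: chrom → iterable of (start, end, score)."""
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, runs in runs_by_chrom.items():
            runs = sorted(runs)
            starts = np.array([r[0] for r in runs], dtype=np.int64)
            ends = np.array([r[1] for r in runs], dtype=np.int64)
            scores = np.array([r[2] for r in runs], dtype=float)
            if len(starts):
                if (starts >= ends).any():
                    raise ValidationError(f"empty run on {chrom}")
                if (starts[1:] < ends[:-1]).any():
                    raise ValidationError(f"overlapping runs on {chrom}")
                if (scores < 0).any() or (scores > 1).any():
                    raise ValidationError(f"score outside [0, 1] on {chrom}")
            self._chroms[chrom] = (starts, ends, scores)

    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def iter_runs(self):
        for chrom in self.chroms():
            starts, ends, scores = self._chroms[chrom]
            for s, e, v in zip(starts, ends, scores):
                yield chrom, int(s), int(e), float(v)

    def mean(self, region: GenomicInterval) -> float:
        """Mean per-base score over ``region``; uncovered bases contribute 0."""
        entry = self._chroms.get(region.chrom)
        if entry is None:
            return 0.0
        starts, ends, scores = entry
        i0 = int(np.searchsorted(ends, region.start, side="right"))
        i1 = int(np.searchsorted(starts, region.end, side="left"))
        if i0 >= i1:
            return 0.0
        ov = np.minimum(ends[i0:i1], region.end) - np.maximum(
            starts[i0:i1], region.start
        )
        total = float((ov * scores[i0:i1]).sum())
        return total / region.length


def mean_conservation(track: ConservationTrack, region: GenomicInterval) -> float:
    return track.mean(region)


def _bp_weighted_mean(track: ConservationTrack, regions: Sequence[GenomicInterval]) -> float:
    total_bp = sum(r.length for r in regions)
    if total_bp == 0:
        raise ValidationError("empty region list")
    return (
        sum(track.mean(r) * r.length for r in regions) / total_bp
    )


def sample_matched_region_sets(
    pool: Sequence[GenomicInterval],
    target_lengths: Sequence[int],
    n_sets: int,
    seed,
) -> list[list[GenomicInterval]]:
    """Draw ``n_sets`` region sets from ``pool`` length-matched to the targets.

    For each target length L a sub-interval of length L is placed uniformly
    over all valid start positions in the pool (each pool interval weighted by
    its number of valid starts), so every set carries the same amount of
    sequence as the prediction set.  ``seed`` may be an int or a numpy
    Generator.
    """
    if n_sets <= 0:
        raise ValidationError("n_sets must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lens = np.array([iv.length for iv in pool], dtype=np.int64)
    sets: list[list[GenomicInterval]] = []
    for _ in range(n_sets):
        regions: list[GenomicInterval] = []
        for L in target_lengths:
            if L <= 0:
                raise ValidationError("target lengths must be positive")
            weights = lens - L + 1
            weights[weights < 0] = 0
            total = int(weights.sum())
            if total == 0:
                raise ValidationError(
                    f"no pool interval is long enough for a {L} bp region"
                )
            idx = int(rng.choice(len(pool), p=weights / total))
            off = int(rng.integers(0, weights[idx]))
            iv = pool[idx]
            regions.append(
                GenomicInterval(iv.chrom, iv.start + off, iv.start + off + L, iv.strand)
            )
        sets.append(regions)
    return sets


@dataclass(frozen=True)
class ConservationComparison:
    ext_mean: float
    utr_set_means: tuple[float, ...]
    intergenic_set_means: tuple[float, ...]
    z: float
    p: float


def conservation_comparison(
    ext_regions: Sequence[GenomicInterval],
    utr_pool: Sequence[GenomicInterval],
    intergenic_pool: Sequence[GenomicInterval],
    track: ConservationTrack,
    *,
    n_sets: int = 100,
    seed: int = 0,
) -> ConservationComparison:
    """Compare prediction conservation against matched random sets.

    ``z`` places the bp-weighted prediction mean on the distribution of the
    intergenic set means (sample sd, n-1 denominator); ``p`` is the one-sided
    upper-tail normal probability.
    """
    ext_mean = _bp_weighted_mean(track, ext_regions)
    target_lengths = [r.length for r in ext_regions]
    ss = np.random.SeedSequence(seed)
    utr_rng, ig_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    utr_sets = sample_matched_region_sets(utr_pool, target_lengths, n_sets, utr_rng)
    ig_sets = sample_matched_region_sets(intergenic_pool, target_lengths, n_sets, ig_rng)
    utr_means = tuple(_bp_weighted_mean(track, s) for s in utr_sets)
    ig_means = tuple(_bp_weighted_mean(track, s) for s in ig_sets)
    sd = float(np.std(ig_means, ddof=1))
    if sd == 0.0:
        raise ComputationError(
            "intergenic set means are constant; Z-statistic undefined"
        )
    z = (ext_mean - float(np.mean(ig_means))) / sd
    p = max(float(norm.sf(z)), _TINY_P)
    return ConservationComparison(
        ext_mean=ext_mean,
        utr_set_means=utr_means,
        intergenic_set_means=ig_means,
        z=z,
        p=p,
    )


_RC = str.maketrans("ACGTN", "TGCAN")


def extract_sequence(sequences, region: GenomicInterval) -> str:
    """Strand-aware region sequence: reverse-complemented on ``-``.

    ``sequences`` maps chromosome name → full chromosome string.
    """
    try:
        chrom_seq = sequences[region.chrom]
    except KeyError:
        raise ValidationError(f"no sequence for chromosome {region.chrom!r}")
    if region.end > len(chrom_seq):
        raise ValidationError(
            f"region {region} extends past the {len(chrom_seq)} bp sequence"
        )
    s = chrom_seq[region.start : region.end].upper()
    if region.strand == "-":
        s = s.translate(_RC)[::-1]
    return s


def confirm_by_tags(
    extended_target: GenomicInterval,
    tags: Sequence[GenomicInterval],
    *,
    max_downstream: Optional[int] = None,
) -> bool:
    """True iff a same-strand 3'-end tag supports the extension.

    A tag confirms when its 3' coordinate falls inside the extended probe
    set's target region or downstream of it in transcript orientation.
    ``max_downstream`` optionally bounds how far downstream (bp beyond the
    target's 3' edge) a tag may fall and still count; the unbounded default
    credits any downstream polyadenylation evidence, which on dense loci can
    pick up tags of unrelated downstream genes.
    """
    for tag in tags:
        if tag.chrom != extended_target.chrom or tag.strand != extended_target.strand:
            continue
        t3 = three_prime_coordinate(tag)
        if extended_target.strand == "+":
            ok = t3 > extended_target.start
            if ok and max_downstream is not None:
                ok = t3 <= extended_target.end + max_downstream
        else:
            ok = t3 < extended_target.end
            if ok and max_downstream is not None:
                ok = t3 >= extended_target.start - max_downstream
        if ok:
            return True
    return False
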