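"""Probe sets, transcripts and the strand-aware pairing logic.

A 3'-biased expression array summarizes ~11 probe pairs into one probe set,
designed near the 3' end of its target transcript.  For every annotated
transcript the screen finds the *primary* probe set (the annotated probe set
whose genomic target is most 3' in transcript orientation) and then asks
whether the single nearest probe set strictly downstream, on the same strand,
is unannotated — such a probe set is a candidate reporter of a 3'UTR that
extends beyond the annotated transcript end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError
from .intervals import GenomicInterval, three_prime_coordinate

logger = logging.getLogger("utrx")


@dataclass(frozen=True)
class ProbeSet:
    """A probe set with one or more genomic target alignments.

    Multi-mapping probe sets (more than one alignment) are removed before
    pairing because their signal cannot be attributed to a single locus.
    """

    id: str
    alignments: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.alignments:
            raise ValidationError(f"probe set {self.id!r} has no alignments")
        object.__setattr__(self, "alignments", tuple(self.alignments))

    @property
    def is_unique(self) -> bool:
        return len(self.alignments) == 1

    @property
    def target(self) -> GenomicInterval:
        """The unique alignment; only meaningful for uniquely-mapping probe sets."""
        if not self.is_unique:
            raise ValidationError(
                f"probe set {self.id!r} maps to {len(self.alignments)} locations"
            )
        return self.alignments[0]


@dataclass(frozen=True)
class Transcript:
    """An annotated gene model with a strand-aware 3' end."""

    id: str
    gene_symbol: str
    span: GenomicInterval
    exons: Optional[tuple[GenomicInterval, ...]] = None

    def __post_init__(self) -> None:
        if self.exons is not None:
            exons = tuple(self.exons)
            for ex in exons:
                if (
                    ex.chrom != self.span.chrom
                    or ex.strand != self.span.strand
                    or ex.start < self.span.start
                    or ex.end > self.span.end
                ):
                    raise ValidationError(
                        f"exon {ex} of {self.id} lies outside its span {self.span}"
                    )
            object.__setattr__(self, "exons", exons)

    @property
    def three_prime(self) -> int:
        return three_prime_coordinate(self.span)


class AnnotationTable:
    """Map probe-set id → set of transcript ids it is annotated to.

    A probe set is *annotated* iff its entry is non-empty.  Probe sets absent
    from the table are treated as unannotated (empty set), matching the
    vendor-annotation-file semantics.
    """

    def __init__(self, data: Mapping[str, Iterable[str]]):
        self._data: dict[str, frozenset[str]] = {
            str(k): frozenset(v) for k, v in data.items()
        }

    def transcripts_of(self, probe_id: str) -> frozenset[str]:
        return self._data.get(probe_id, frozenset())

    def is_annotated(self, probe_id: str) -> bool:
        return bool(self._data.get(probe_id))

    def items(self):
        return self._data.items()

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._data

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationTable) and self._data == other._data


@dataclass(frozen=True)
class PipelineParameters:
    """Tunable thresholds of the detection screen.

    expression_threshold
        log2 signal a probe set must strictly exceed in at least one array to
        count as expressed above noise (default 6, i.e. raw signal > 64).
    correlation_cutoff
        Pearson r a pair must strictly exceed to be called co-expressed
        (default 0.6).
    motif_max_region_len
        only extension regions strictly shorter than this (bp) enter motif
        and conservation characterization (default 1000), which limits the
        inclusion of spliced-out intronic sequence.
    n_random_sets
        number of matched random region sets per pool for the conservation
        comparison (default 100).
    n_random_pairs
        number of random probe-set pairs drawn for the correlation null
        (default 100000).
    """

    expression_threshold: float = 6.0
    correlation_cutoff: float = 0.6
    motif_max_region_len: int = 1000
    n_random_sets: int = 100
    n_random_pairs: int = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.expression_threshold):
            raise ValidationError("expression_threshold must be finite")
        if not (-1.0 <= self.correlation_cutoff <= 1.0):
            raise ValidationError("correlation_cutoff must lie in [-1, 1]")
        for name in ("motif_max_region_len", "n_random_sets", "n_random_pairs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def remove_multimapping(probesets: Sequence[ProbeSet]) -> list[ProbeSet]:
    """Drop probe sets aligning to more than one genomic location.

    Order-preserving and idempotent.
    """
    return [ps for ps in probesets if ps.is_unique]


def select_representative_transcripts(
    transcripts: Sequence[Transcript],
) -> dict[str, Transcript]:
    """Pick, per gene symbol, the transcript whose annotation extends most 3'.

    On ``+`` this is the transcript with the maximal ``end``; on ``-`` the one
    with the minimal ``start``.  Ties go to the lexicographically smallest
    transcript id.  A symbol whose transcripts disagree on chromosome or
    strand is rejected with a diagnostic and contributes nothing.
    """
    by_symbol: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_symbol.setdefault(t.gene_symbol, []).append(t)

    chosen: dict[str, Transcript] = {}
    for symbol, ts in by_symbol.items():
        keys = {(t.span.chrom, t.span.strand) for t in ts}
        if len(keys) > 1:
            logger.warning(
                "gene symbol %r maps to multiple chromosome/strand combinations %s; skipped",
                symbol,
                sorted(keys),
            )
            continue
        strand = ts[0].span.strand
        if strand == "+":
            chosen[symbol] = min(ts, key=lambda t: (-t.span.end, t.id))
        else:
            chosen[symbol] = min(ts, key=lambda t: (t.span.start, t.id))
    return chosen


def find_primary_probeset(
    t: Transcript,
    annotated: AnnotationTable,
    probesets: Sequence[ProbeSet],
) -> Optional[ProbeSet]:
    """The probe set annotated to ``t`` whose target is most 3' in t's orientation.

    Only uniquely-mapping probe sets on the transcript's chromosome and strand
    are considered.  Ties are broken by the smallest probe-set id.  Returns
    ``None`` when nothing is annotated to ``t``.
    """
    candidates = [
        ps
        for ps in probesets
        if ps.is_unique
        and t.id in annotated.transcripts_of(ps.id)
        and ps.target.chrom == t.span.chrom
        and ps.target.strand == t.span.strand
    ]
    if not candidates:
        return None
    sign = 1 if t.span.strand == "+" else -1
    return min(
        candidates,
        key=lambda ps: (-sign * three_prime_coordinate(ps.target), ps.id),
    )


def find_downstream_candidate(
    t: Transcript,
    primary: ProbeSet,
    probesets: Sequence[ProbeSet],
    annotated: AnnotationTable,
    *,
    annotate_by_overlap: bool = False,
    transcripts: Optional[Sequence[Transcript]] = None,
) -> Optional[ProbeSet]:
    """The single nearest probe set strictly downstream of the primary target.

    "Strictly downstream" means the candidate's 5'-most edge (in transcript
    orientation) lies beyond the primary target's 3' coordinate; overlapping
    or abutting targets do not qualify.  Exactly one candidate — the nearest,
    ties by smallest id — is evaluated: if it is annotated (non-empty entry in
    the table, or, with ``annotate_by_overlap``, a same-strand overlap with
    any transcript span) the transcript yields no pair rather than skipping
    further downstream.
    """
    strand = t.span.strand
    p3 = three_prime_coordinate(primary.target)

    def downstream_gap(ps: ProbeSet) -> Optional[int]:
        iv = ps.target
        if iv.chrom != t.span.chrom or iv.strand != strand:
            return None
        if strand == "+":
            gap = iv.start - p3
        else:
            gap = p3 - iv.end
        return gap if gap > 0 else None

    best: Optional[tuple[int, str, ProbeSet]] = None
    for ps in probesets:
        if not ps.is_unique or ps.id == primary.id:
            continue
        gap = downstream_gap(ps)
        if gap is None:
            continue
        key = (gap, ps.id)
        if best is None or key < (best[0], best[1]):
            best = (gap, ps.id, ps)
    if best is None:
        return None
    candidate = best[2]

    if annotated.is_annotated(candidate.id):
        return None
    if annotate_by_overlap and transcripts is not None:
        for tr in transcripts:
            if (
                tr.span.strand == candidate.target.strand
                and tr.span.overlaps(candidate.target)
            ):
                return None
    return candidate
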