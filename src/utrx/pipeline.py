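"""The end-to-end detection screen.

Stages, in order, with the count of transcripts surviving each:

1. ``transcripts`` — annotated transcripts considered;
2. ``probe_set_pair`` — transcripts with a primary probe set and a nearest
   strictly-downstream, same-strand, unannotated probe set;
3. ``above_noise`` — pairs whose two members both exceed the expression
   threshold in at least one array;
4. ``correlated`` — pairs whose Pearson r strictly exceeds the cutoff;
5. ``unique_genes`` — one prediction per gene symbol, keeping the transcript
   whose annotation already extends most 3'.

Pairs where only the downstream member is expressed above noise are handled
by :func:`rescue_low_primary_pairs` — the primary probe set may sit far from
the true 3' end and suffer from the labeling-efficiency gradient — but these
noisier calls are reported separately and never merged into the main list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .annotation import (
    AnnotationTable,
    PipelineParameters,
    ProbeSet,
    Transcript,
    find_downstream_candidate,
    find_primary_probeset,
    remove_multimapping,
    select_representative_transcripts,
)
from .errors import UndefinedCorrelationError, ValidationError
from .expression import ExpressionMatrix, above_noise, pearson
from .regions import pair_distance

logger = logging.getLogger("utrx")


@dataclass(frozen=True)
class ProbeSetPair:
    """A primary/extended candidate pair with its screening statistics."""

    transcript_id: str
    gene_symbol: str
    primary_id: str
    extended_id: str
    pearson_r: Optional[float]
    distance: int
    primary_above_noise: bool
    extended_above_noise: bool

    def __post_init__(self) -> None:
        if self.pearson_r is not None and not (-1.0 <= self.pearson_r <= 1.0):
            raise ValidationError(f"pearson_r {self.pearson_r} outside [-1, 1]")
        if self.distance < 0:
            raise ValidationError("distance must be non-negative")


@dataclass
class PipelineReport:
    """Stage names with surviving counts, plus the final predictions.

    ``candidate_pairs`` keeps every pair that reached the correlation stage
    (both members above noise, r computed), so sub-cutoff pairs remain
    visible for diagnostics and histograms.
    """

    stages: list[tuple[str, int]] = field(default_factory=list)
    predictions: list[ProbeSetPair] = field(default_factory=list)
    candidate_pairs: list[ProbeSetPair] = field(default_factory=list)

    def stage_count(self, name: str) -> int:
        for stage, count in self.stages:
            if stage == name:
                return count
        raise KeyError(name)


def _candidate_pairs(
    transcripts: Sequence[Transcript],
    probesets: Sequence[ProbeSet],
    annotation: AnnotationTable,
    *,
    annotate_by_overlap: bool = False,
) -> list[tuple[Transcript, ProbeSet, ProbeSet]]:
    """(transcript, primary, extended-candidate) triples after pairing."""
    unique = remove_multimapping(probesets)
    triples = []
    for t in transcripts:
        primary = find_primary_probeset(t, annotation, unique)
        if primary is None:
            continue
        candidate = find_downstream_candidate(
            t,
            primary,
            unique,
            annotation,
            annotate_by_overlap=annotate_by_overlap,
            transcripts=transcripts if annotate_by_overlap else None,
        )
        if candidate is None:
            continue
        triples.append((t, primary, candidate))
    return triples


def _score_pair(
    t: Transcript,
    primary: ProbeSet,
    candidate: ProbeSet,
    m: ExpressionMatrix,
    threshold: float,
) -> Optional[ProbeSetPair]:
    """Noise flags + correlation for one pair; None when unscorable."""
    for pid in (primary.id, candidate.id):
        if pid not in m:
            logger.warning(
                "probe set %s (transcript %s) missing from expression matrix; pair dropped",
                pid,
                t.id,
            )
            return None
    prow = m.row(primary.id)
    crow = m.row(candidate.id)
    p_ok = above_noise(prow, threshold)
    c_ok = above_noise(crow, threshold)
    r: Optional[float] = None
    if p_ok and c_ok or (c_ok and not p_ok):
        try:
            r = pearson(prow, crow)
        except UndefinedCorrelationError:
            logger.warning(
                "zero-variance profile for pair %s/%s; pair dropped",
                primary.id,
                candidate.id,
            )
            return None
    return ProbeSetPair(
        transcript_id=t.id,
        gene_symbol=t.gene_symbol,
        primary_id=primary.id,
        extended_id=candidate.id,
        pearson_r=r,
        distance=pair_distance(primary.target, candidate.target),
        primary_above_noise=p_ok,
        extended_above_noise=c_ok,
    )


def detect_extensions(
    transcripts: Sequence[Transcript],
    probesets: Sequence[ProbeSet],
    annotation: AnnotationTable,
    m: ExpressionMatrix,
    params: PipelineParameters,
    *,
    annotate_by_overlap: bool = False,
) -> PipelineReport:
    """Run the full screen and return predictions plus per-stage counts."""
    report = PipelineReport()
    report.stages.append(("transcripts", len(transcripts)))

    triples = _candidate_pairs(
        transcripts, probesets, annotation, annotate_by_overlap=annotate_by_overlap
    )
    report.stages.append(("probe_set_pair", len(triples)))

    scored = []
    for t, primary, candidate in triples:
        pair = _score_pair(t, primary, candidate, m, params.expression_threshold)
        if pair is not None:
            scored.append((t, pair))
    noisy_ok = [
        (t, p) for t, p in scored if p.primary_above_noise and p.extended_above_noise
    ]
    report.stages.append(("above_noise", len(noisy_ok)))
    report.candidate_pairs = [p for _, p in noisy_ok]

    correlated = [
        (t, p) for t, p in noisy_ok if p.pearson_r is not None
        and p.pearson_r > params.correlation_cutoff
    ]
    report.stages.append(("correlated", len(correlated)))

    representatives = select_representative_transcripts([t for t, _ in correlated])
    by_tid = {t.id: p for t, p in correlated}
    predictions = [
        by_tid[t.id] for t in representatives.values() if t.id in by_tid
    ]
    predictions.sort(key=lambda p: (p.gene_symbol, p.transcript_id))
    report.predictions = predictions
    report.stages.append(("unique_genes", len(predictions)))
    return report


def rescue_low_primary_pairs(
    transcripts: Sequence[Transcript],
    probesets: Sequence[ProbeSet],
    annotation: AnnotationTable,
    m: ExpressionMatrix,
    params: PipelineParameters,
    *,
    annotate_by_overlap: bool = False,
) -> list[ProbeSetPair]:
    """Correlated pairs where only the downstream member passes the noise filter.

    Disjoint from the main predictions by construction; returned separately
    because the low primary signal makes these calls noisier.
    """
    triples = _candidate_pairs(
        transcripts, probesets, annotation, annotate_by_overlap=annotate_by_overlap
    )
    rescued = []
    for t, primary, candidate in triples:
        pair = _score_pair(t, primary, candidate, m, params.expression_threshold)
        if pair is None:
            continue
        if (
            pair.extended_above_noise
            and not pair.primary_above_noise
            and pair.pearson_r is not None
            and pair.pearson_r > params.correlation_cutoff
        ):
            rescued.append(pair)
    rescued.sort(key=lambda p: (p.gene_symbol, p.transcript_id))
    return rescued
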