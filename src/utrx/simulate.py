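"""Synthetic input bundles with a planted ground truth.

The generator emulates the structure of a 3'-biased tissue-compendium
experiment: a few dozen tissues with 3–5 replicates each (70 arrays by
default), log2 signals with an above-noise threshold around 6, annotated
gene models each carrying a primary probe set in the 3'UTR, a planted
fraction of genes with an unannotated downstream probe set reporting a true
3'UTR extension, and decoy unannotated probe sets with independent
expression.  Conservation tracks draw per-base scores around class means
(known 3'UTR ≈ 0.233, intergenic ≈ 0.124, planted extensions ≈ 0.26) and
sequences optionally carry planted polyadenylation motifs inside extensions.

Correlation is planted through a shared latent per-tissue effect rather than
by copying profiles, so the random-pair null keeps a realistic,
non-degenerate tail.  Pair members additionally differ by a consistent
signal-intensity shift, mimicking the 3' labeling-efficiency gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import AnnotationTable, ProbeSet, Transcript
from .errors import ValidationError
from .expression import ExpressionMatrix
from .intervals import GenomicInterval
from .regions import ConservationTrack

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 200
    fraction_with_extension: float = 0.3
    n_tissues: int = 22
    replicates_per_tissue: tuple[int, int] = (3, 5)
    n_samples: int = 70
    tissue_effect_sd: float = 1.5
    replicate_noise_sd: float = 0.4
    planted_pair_correlation: float = 0.9
    background_signal_mean: float = 8.0
    background_signal_sd: float = 1.0
    utr_conservation_mean: float = 0.233
    intergenic_conservation_mean: float = 0.124
    extension_conservation_mean: float = 0.26
    conservation_sd: float = 0.1
    motif_plant_rate: float = 0.7
    tag_fraction: float = 0.4
    fraction_low_primary: float = 0.0
    n_chromosomes: int = 4
    chromosome_length: Optional[int] = None
    slot_length: int = 20_000
    gene_span: int = 5_000
    utr_length: int = 1_000
    probe_target_length: int = 25
    extension_length_range: tuple[int, int] = (200, 900)
    decoy_offset_range: tuple[int, int] = (1500, 3000)
    intergenic_region_length: int = 1_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_with_extension", "motif_plant_rate", "tag_fraction",
                     "fraction_low_primary"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name in ("tissue_effect_sd", "replicate_noise_sd",
                     "background_signal_sd", "conservation_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("utr_conservation_mean", "intergenic_conservation_mean",
                     "extension_conservation_mean"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.planted_pair_correlation <= 1.0):
            raise ValidationError("planted_pair_correlation must lie in [0, 1]")
        if self.n_genes <= 0 or self.n_tissues <= 0 or self.n_samples < 2:
            raise ValidationError("counts must be positive (>= 2 samples)")
        lo, hi = self.replicates_per_tissue
        if not (self.n_tissues * lo <= self.n_samples <= self.n_tissues * hi):
            raise ValidationError(
                f"{self.n_samples} samples cannot be split over {self.n_tissues} "
                f"tissues with {lo}-{hi} replicates"
            )


@dataclass
class GeneTruth:
    gene_symbol: str
    transcript_id: str
    span: GenomicInterval
    utr: GenomicInterval
    primary_id: str
    primary_target: GenomicInterval
    has_extension: bool
    extended_id: Optional[str] = None
    extended_target: Optional[GenomicInterval] = None
    extension_region: Optional[GenomicInterval] = None
    planted_correlation: Optional[float] = None
    low_primary: bool = False
    decoy_id: Optional[str] = None
    decoy_target: Optional[GenomicInterval] = None
    has_tag: bool = False
    motif_planted: bool = False


@dataclass
class TruthTable:
    genes: list[GeneTruth]
    multimapper_ids: list[str]
    chrom_lengths: dict[str, int]
    intergenic_pool: list[GenomicInterval]

    @property
    def utr_pool(self) -> list[GenomicInterval]:
        return [g.utr for g in self.genes]

    @property
    def extension_genes(self) -> list[GeneTruth]:
        return [g for g in self.genes if g.has_extension]


@dataclass
class SyntheticBundle:
    """Everything the detection and characterization modules consume."""

    probesets: list[ProbeSet]
    transcripts: list[Transcript]
    annotation: AnnotationTable
    expression: ExpressionMatrix
    tissues: dict[str, str]
    conservation: ConservationTrack
    sequences: dict[str, str]
    tags: list[GenomicInterval]
    truth: TruthTable


def _streams(cfg: SyntheticConfig) -> tuple[np.random.Generator, ...]:
    """Independent, reproducible streams: geometry, expression, track/sequence."""
    children = np.random.SeedSequence(cfg.rng_seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _layout(cfg: SyntheticConfig) -> TruthTable:
    """Place gene models, probe targets, decoys and pools on synthetic chromosomes."""
    rng = _streams(cfg)[0]
    ext_max = cfg.extension_length_range[1]
    decoy_max = cfg.decoy_offset_range[1] + cfg.probe_target_length
    required = 1000 + cfg.gene_span + max(ext_max, decoy_max) + 500 + cfg.intergenic_region_length
    if cfg.slot_length < required:
        raise ValidationError(
            f"slot_length {cfg.slot_length} too small for the layout "
            f"(needs >= {required} bp)"
        )
    genes_per_chrom = math.ceil(cfg.n_genes / cfg.n_chromosomes)
    chrom_len = genes_per_chrom * cfg.slot_length
    if cfg.chromosome_length is not None:
        slots = cfg.chromosome_length // cfg.slot_length
        if slots * cfg.n_chromosomes < cfg.n_genes:
            raise ValidationError(
                f"{cfg.n_genes} genes do not fit on {cfg.n_chromosomes} "
                f"chromosomes of {cfg.chromosome_length} bp"
            )
        chrom_len = cfg.chromosome_length
        genes_per_chrom = slots
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chrom_lengths = {c: chrom_len for c in chroms}

    n_ext = round(cfg.fraction_with_extension * cfg.n_genes)
    ext_idx = set(rng.choice(cfg.n_genes, size=n_ext, replace=False).tolist())
    n_low = round(cfg.fraction_low_primary * n_ext)
    low_idx = set(rng.choice(sorted(ext_idx), size=n_low, replace=False).tolist()) if n_low else set()

    plen = cfg.probe_target_length
    genes: list[GeneTruth] = []
    ig_pool: list[GenomicInterval] = []
    for i in range(cfg.n_genes):
        chrom = chroms[i // genes_per_chrom]
        slot0 = (i % genes_per_chrom) * cfg.slot_length
        slot1 = slot0 + cfg.slot_length
        strand = "+" if rng.random() < 0.5 else "-"
        ext_len = int(rng.integers(*cfg.extension_length_range))
        decoy_off = int(rng.integers(*cfg.decoy_offset_range))
        has_ext = i in ext_idx
        if strand == "+":
            span = GenomicInterval(chrom, slot0 + 500, slot0 + 500 + cfg.gene_span, "+")
            utr = GenomicInterval(chrom, span.end - cfg.utr_length, span.end, "+")
            primary = GenomicInterval(chrom, span.end - 75, span.end - 75 + plen, "+")
            if has_ext:
                ext_region = GenomicInterval(chrom, span.end, span.end + ext_len, "+")
                ext_target = GenomicInterval(chrom, ext_region.end - plen, ext_region.end, "+")
            decoy = GenomicInterval(chrom, span.end + decoy_off, span.end + decoy_off + plen, "+")
            clear = span.end + max(ext_max, decoy_max)
            ig = GenomicInterval(chrom, clear + 500, clear + 500 + cfg.intergenic_region_length, "+")
        else:
            span = GenomicInterval(chrom, slot1 - 500 - cfg.gene_span, slot1 - 500, "-")
            utr = GenomicInterval(chrom, span.start, span.start + cfg.utr_length, "-")
            primary = GenomicInterval(chrom, span.start + 50, span.start + 50 + plen, "-")
            if has_ext:
                ext_region = GenomicInterval(chrom, span.start - ext_len, span.start, "-")
                ext_target = GenomicInterval(chrom, ext_region.start, ext_region.start + plen, "-")
            decoy = GenomicInterval(chrom, span.start - decoy_off - plen, span.start - decoy_off, "-")
            clear = span.start - max(ext_max, decoy_max)
            ig = GenomicInterval(chrom, clear - 500 - cfg.intergenic_region_length, clear - 500, "+")
        gt = GeneTruth(
            gene_symbol=f"gene{i:05d}",
            transcript_id=f"T{i:05d}",
            span=span,
            utr=utr,
            primary_id=f"ps{i:05d}_at",
            primary_target=primary,
            has_extension=has_ext,
            low_primary=i in low_idx,
        )
        if has_ext:
            gt.extended_id = f"ps{i:05d}_x_at"
            gt.extended_target = ext_target
            gt.extension_region = ext_region
            gt.planted_correlation = cfg.planted_pair_correlation
        else:
            gt.decoy_id = f"ps{i:05d}_d_at"
            gt.decoy_target = decoy
        genes.append(gt)
        ig_pool.append(ig)

    n_multi = max(1, cfg.n_genes // 20)
    multis = [f"mm{j:04d}_at" for j in range(n_multi)]
    return TruthTable(
        genes=genes,
        multimapper_ids=multis,
        chrom_lengths=chrom_lengths,
        intergenic_pool=ig_pool,
    )


def _sample_layout(cfg: SyntheticConfig) -> tuple[list[str], dict[str, str], np.ndarray]:
    """Sample ids, sample→tissue map, and tissue index per sample."""
    base = cfg.n_samples // cfg.n_tissues
    rem = cfg.n_samples - base * cfg.n_tissues
    samples: list[str] = []
    tissues: dict[str, str] = {}
    tidx: list[int] = []
    j = 0
    for k in range(cfg.n_tissues):
        reps = base + (1 if k < rem else 0)
        for _ in range(reps):
            sid = f"s{j + 1:03d}"
            samples.append(sid)
            tissues[sid] = f"tissue{k + 1:02d}"
            tidx.append(k)
            j += 1
    return samples, tissues, np.asarray(tidx)


def generate_expression(truth: TruthTable, cfg: SyntheticConfig) -> ExpressionMatrix:
    """log2 signals for every probe set in the bundle.

    Each probe set's profile is a per-gene latent tissue effect (constant
    across a tissue's replicates) plus a probe-set baseline and per-array
    noise.  A planted pair shares the tissue effect; the private jitter
    variance is chosen so the expected pair correlation equals
    ``planted_pair_correlation`` given the tissue-effect and replicate-noise
    variances.  Low-primary genes have their primary profile compressed onto
    a low baseline so it fails the noise filter while keeping the planted
    correlation intact.
    """
    rng = _streams(cfg)[1]
    samples, tissues, tidx = _sample_layout(cfg)
    n = len(samples)
    rho = cfg.planted_pair_correlation
    st2 = cfg.tissue_effect_sd**2
    sr2 = cfg.replicate_noise_sd**2
    if rho > 0:
        pair_jitter = math.sqrt(max(st2 * (1.0 - rho) / rho - sr2, 0.0) + sr2)
    else:
        pair_jitter = None  # independent effects instead

    rows: dict[str, np.ndarray] = {}

    def background_row() -> np.ndarray:
        eff = rng.normal(0.0, cfg.tissue_effect_sd, cfg.n_tissues)[tidx]
        base = rng.normal(cfg.background_signal_mean, cfg.background_signal_sd)
        return base + eff + rng.normal(0.0, cfg.replicate_noise_sd, n)

    for g in truth.genes:
        shared = rng.normal(0.0, cfg.tissue_effect_sd, cfg.n_tissues)[tidx]
        base = rng.normal(cfg.background_signal_mean, cfg.background_signal_sd)
        if g.has_extension:
            if pair_jitter is None:
                p_noise = rng.normal(0.0, cfg.tissue_effect_sd, cfg.n_tissues)[tidx]
                c_noise = rng.normal(0.0, cfg.tissue_effect_sd, cfg.n_tissues)[tidx]
            else:
                p_noise = rng.normal(0.0, pair_jitter, n)
                c_noise = rng.normal(0.0, pair_jitter, n)
            shift = rng.normal(0.8, 0.4)
            primary_row = base + shared + p_noise
            extended_row = base + shift + shared + c_noise
            if g.low_primary:
                # compress onto a low baseline; correlation is scale-invariant
                primary_row = 3.0 + 0.25 * (shared + p_noise)
            rows[g.primary_id] = primary_row
            rows[g.extended_id] = extended_row
        else:
            rows[g.primary_id] = base + shared + rng.normal(0.0, cfg.replicate_noise_sd, n)
            rows[g.decoy_id] = background_row()
    for mid in truth.multimapper_ids:
        rows[mid] = background_row()

    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return ExpressionMatrix(values, tissues)


def _random_sequence(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())


_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp_bytes(b: bytes) -> bytes:
    return b.translate(_COMP)[::-1]


def generate_conservation_and_sequence(
    truth: TruthTable, cfg: SyntheticConfig
) -> tuple[ConservationTrack, dict[str, str], list[GenomicInterval]]:
    """Conservation track, chromosome sequences and 3'-end tag intervals.

    Per-base scores are drawn i.i.d. from a clipped normal around the class
    mean (known 3'UTR / planted extension / intergenic).  A mammalian polyA
    motif instance is planted near the 3' end of each extension with
    probability ``motif_plant_rate``; 3'-end tags are emitted at the planted
    extension ends for ``tag_fraction`` of extension genes.
    """
    rng = _streams(cfg)[2]
    seqs = {c: _random_sequence(rng, L) for c, L in truth.chrom_lengths.items()}

    def class_runs(iv: GenomicInterval, mean: float) -> list[tuple[int, int, float]]:
        vals = np.clip(
            rng.normal(mean, cfg.conservation_sd, iv.length), 0.0, 1.0
        )
        pos = range(iv.start, iv.end)
        return list(zip(pos, (p + 1 for p in pos), vals.tolist()))

    runs: dict[str, list[tuple[int, int, float]]] = {c: [] for c in truth.chrom_lengths}
    for g in truth.genes:
        runs[g.utr.chrom].extend(class_runs(g.utr, cfg.utr_conservation_mean))
    for g in truth.extension_genes:
        runs[g.extension_region.chrom].extend(
            class_runs(g.extension_region, cfg.extension_conservation_mean)
        )
    for iv in truth.intergenic_pool:
        runs[iv.chrom].extend(class_runs(iv, cfg.intergenic_conservation_mean))
    track = ConservationTrack(runs)

    for g in truth.extension_genes:
        if rng.random() < cfg.motif_plant_rate:
            g.motif_planted = True
            instance = (
                b"AATAAA"
                + _BASES[rng.integers(0, 4, size=12)].tobytes()
                + b"GTGTGTGTGT"
            )
            region = g.extension_region
            # 40 bp upstream of the extension 3' end, in sense orientation
            sense_pos = region.length - 40
            if sense_pos < 0:
                sense_pos = 0
            if region.strand == "+":
                start = region.start + sense_pos
                seqs[region.chrom][start : start + len(instance)] = instance
            else:
                end = region.end - sense_pos
                rc = _revcomp_bytes(instance)
                seqs[region.chrom][end - len(rc) : end] = rc

    tags: list[GenomicInterval] = []
    for g in truth.extension_genes:
        if rng.random() < cfg.tag_fraction:
            g.has_tag = True
            delta = int(rng.integers(0, 50))
            region = g.extension_region
            if region.strand == "+":
                tags.append(
                    GenomicInterval(region.chrom, region.end + delta - 20,
                                    region.end + delta, "+")
                )
            else:
                tags.append(
                    GenomicInterval(region.chrom, region.start - delta,
                                    region.start - delta + 20, "-")
                )

    sequences = {c: b.decode("ascii") for c, b in seqs.items()}
    return track, sequences, tags


def generate_dataset(cfg: SyntheticConfig) -> tuple[SyntheticBundle, TruthTable]:
    """Complete, mutually consistent input bundle plus its ground truth."""
    truth = _layout(cfg)

    probesets: list[ProbeSet] = []
    transcripts: list[Transcript] = []
    ann: dict[str, set[str]] = {}
    for g in truth.genes:
        transcripts.append(
            Transcript(id=g.transcript_id, gene_symbol=g.gene_symbol, span=g.span)
        )
        probesets.append(ProbeSet(g.primary_id, (g.primary_target,)))
        ann[g.primary_id] = {g.transcript_id}
        if g.has_extension:
            probesets.append(ProbeSet(g.extended_id, (g.extended_target,)))
            ann[g.extended_id] = set()
        else:
            probesets.append(ProbeSet(g.decoy_id, (g.decoy_target,)))
            ann[g.decoy_id] = set()
    chroms = sorted(truth.chrom_lengths)
    for j, mid in enumerate(truth.multimapper_ids):
        c1, c2 = chroms[j % len(chroms)], chroms[(j + 1) % len(chroms)]
        slot0 = (j % max(1, len(truth.genes) // len(chroms))) * cfg.slot_length
        a1 = GenomicInterval(c1, slot0 + 100, slot0 + 100 + cfg.probe_target_length, "+")
        a2 = GenomicInterval(c2, slot0 + 100, slot0 + 100 + cfg.probe_target_length, "+")
        probesets.append(ProbeSet(mid, (a1, a2)))
        ann[mid] = set()

    expression = generate_expression(truth, cfg)
    track, sequences, tags = generate_conservation_and_sequence(truth, cfg)

    bundle = SyntheticBundle(
        probesets=probesets,
        transcripts=transcripts,
        annotation=AnnotationTable(ann),
        expression=expression,
        tissues=dict(expression.tissues),
        conservation=track,
        sequences=sequences,
        tags=tags,
        truth=truth,
    )
    return bundle, truth
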