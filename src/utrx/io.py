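"""Readers/writers for the interchange formats and the run manifest.

Everything is plain text: BED6 (probe-set alignments, one line per
alignment; 3'-end tags), BED12 plus a two-column symbol table (transcripts),
TSV (annotation table, expression matrix, tissue map, predictions),
bedGraph (conservation) and FASTA (sequences).  Coordinates are BED
half-open throughout; parsers reject out-of-contract values with the file
and 1-based line number rather than coercing them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AnnotationTable, ProbeSet, Transcript
from .errors import ValidationError
from .expression import ExpressionMatrix
from .intervals import GenomicInterval
from .pipeline import PipelineReport, ProbeSetPair
from .regions import ConservationTrack
from .simulate import SyntheticBundle, TruthTable

_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]
_BED12_COLS = _BED6_COLS + [
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]

PREDICTION_COLUMNS = [
    "gene_symbol", "transcript_id", "primary_probeset", "extended_probeset",
    "pearson_r", "distance_bp", "ensembl_supported", "netaffx_supported",
]


def _read_table(path, columns: list[str], kind: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    if df.shape[1] < len(columns):
        raise ValidationError(
            f"{path}: expected {len(columns)} columns for {kind}, found {df.shape[1]}"
        )
    df = df.iloc[:, : len(columns)]
    df.columns = columns
    return df


def _parse_intervals(df: pd.DataFrame, path) -> list[GenomicInterval]:
    out = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError:
            raise ValidationError(f"{path}:{line_no}: non-integer coordinates")
        if not (0 <= start < end):
            raise ValidationError(
                f"{path}:{line_no}: require 0 <= start < end, got {start}, {end}"
            )
        strand = row.strand
        if strand not in ("+", "-"):
            raise ValidationError(f"{path}:{line_no}: bad strand {strand!r}")
        out.append(GenomicInterval(row.chrom, start, end, strand))
    return out


def read_bed6(path) -> list[tuple[str, GenomicInterval]]:
    df = _read_table(path, _BED6_COLS, "BED6")
    ivs = _parse_intervals(df, path)
    return list(zip(df["name"].tolist(), ivs))


def write_bed6(records: Iterable[tuple[str, GenomicInterval]], path) -> None:
    with open(path, "w") as fh:
        for name, iv in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_probesets_bed(path) -> list[ProbeSet]:
    """Group BED6 lines by name; multi-mapping probe sets have several lines."""
    grouped: dict[str, list[GenomicInterval]] = {}
    for name, iv in read_bed6(path):
        grouped.setdefault(name, []).append(iv)
    return [ProbeSet(name, tuple(ivs)) for name, ivs in grouped.items()]


def write_probesets_bed(probesets: Sequence[ProbeSet], path) -> None:
    write_bed6(
        ((ps.id, iv) for ps in probesets for iv in ps.alignments), path
    )


def read_symbols_tsv(path) -> dict[str, str]:
    df = _read_table(path, ["transcript_id", "gene_symbol"], "symbol table")
    return dict(zip(df["transcript_id"], df["gene_symbol"]))


def write_symbols_tsv(symbols: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for tid, sym in symbols.items():
            fh.write(f"{tid}\t{sym}\n")


def read_transcripts_bed12(path, symbols_path) -> list[Transcript]:
    df = _read_table(path, _BED12_COLS, "BED12")
    ivs = _parse_intervals(df, path)
    symbols = read_symbols_tsv(symbols_path)
    out = []
    for line_no, (row, span) in enumerate(zip(df.itertuples(index=False), ivs), start=1):
        tid = row.name
        if tid not in symbols:
            raise ValidationError(
                f"{path}:{line_no}: transcript {tid!r} missing from symbol table"
            )
        sizes = [int(s) for s in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(s) for s in str(row.blockStarts).rstrip(",").split(",")]
        if len(sizes) != len(starts) or len(sizes) != int(row.blockCount):
            raise ValidationError(f"{path}:{line_no}: inconsistent block definition")
        exons = tuple(
            GenomicInterval(span.chrom, span.start + off, span.start + off + size, span.strand)
            for off, size in zip(starts, sizes)
        )
        out.append(Transcript(id=tid, gene_symbol=symbols[tid], span=span, exons=exons))
    return out


def write_transcripts_bed12(transcripts: Sequence[Transcript], path, symbols_path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            span = t.span
            exons = t.exons if t.exons else (span,)
            sizes = ",".join(str(e.length) for e in exons)
            starts = ",".join(str(e.start - span.start) for e in exons)
            fh.write(
                f"{span.chrom}\t{span.start}\t{span.end}\t{t.id}\t0\t{span.strand}"
                f"\t{span.start}\t{span.end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )
    write_symbols_tsv({t.id: t.gene_symbol for t in transcripts}, symbols_path)


def read_annotation_tsv(path) -> AnnotationTable:
    data: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts.append("")
            pid, tids = parts[0], parts[1]
            if pid in data:
                raise ValidationError(f"{path}:{line_no}: duplicate probe set {pid!r}")
            data[pid] = {t for t in tids.split(",") if t}
    return AnnotationTable(data)


def write_annotation_tsv(table: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        for pid, tids in table.items():
            fh.write(f"{pid}\t{','.join(sorted(tids))}\n")


def read_expression_tsv(expr_path, tissues_path=None) -> ExpressionMatrix:
    df = pd.read_csv(expr_path, sep="\t", index_col=0, float_precision="round_trip")
    tissues = None
    if tissues_path is not None:
        tdf = _read_table(tissues_path, ["sample", "tissue"], "tissue map")
        tissues = dict(zip(tdf["sample"], tdf["tissue"]))
    try:
        return ExpressionMatrix(df, tissues)
    except ValidationError as exc:
        raise ValidationError(f"{expr_path}: {exc}") from exc


def write_expression_tsv(m: ExpressionMatrix, expr_path, tissues_path=None) -> None:
    df = m.values.copy()
    df.index.name = "probe_set_id"
    # shortest round-trip repr keeps the matrix lossless through the TSV
    df.to_csv(expr_path, sep="\t", float_format=lambda x: repr(float(x)))
    if tissues_path is not None and m.tissues is not None:
        with open(tissues_path, "w") as fh:
            for sample, tissue in m.tissues.items():
                fh.write(f"{sample}\t{tissue}\n")


def read_bedgraph(path) -> ConservationTrack:
    df = _read_table(path, ["chrom", "start", "end", "score"], "bedGraph")
    runs: dict[str, list[tuple[int, int, float]]] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end, score = int(row.start), int(row.end), float(row.score)
        except ValueError:
            raise ValidationError(f"{path}:{line_no}: malformed bedGraph line")
        if not (0 <= start < end):
            raise ValidationError(f"{path}:{line_no}: bad run [{start}, {end})")
        if not (0.0 <= score <= 1.0):
            raise ValidationError(f"{path}:{line_no}: score {score} outside [0, 1]")
        runs.setdefault(row.chrom, []).append((start, end, score))
    return ConservationTrack(runs)


def write_bedgraph(track: ConservationTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, score in track.iter_runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{score!r}\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_tags_bed(path) -> list[GenomicInterval]:
    return [iv for _, iv in read_bed6(path)]


@dataclass
class InputBundle:
    """Parsed, cross-validated inputs for a detection run."""

    probesets: list[ProbeSet]
    transcripts: list[Transcript]
    annotation: AnnotationTable
    expression: ExpressionMatrix
    conservation: Optional[ConservationTrack] = None
    sequences: Optional[dict[str, str]] = None
    tags: Optional[list[GenomicInterval]] = None


BUNDLE_FILES = {
    "probesets": "probesets.bed",
    "transcripts": "transcripts.bed12",
    "symbols": "symbols.tsv",
    "annotation": "annotation.tsv",
    "expr": "expr.tsv",
    "tissues": "tissues.tsv",
    "conservation": "cons.bedGraph",
    "fasta": "genome.fa",
    "tags": "tags.bed",
}


def load_bundle(
    directory=None,
    *,
    probesets=None,
    transcripts=None,
    symbols=None,
    annotation=None,
    expr=None,
    tissues=None,
    conservation=None,
    fasta=None,
    tags=None,
) -> InputBundle:
    """Load and cross-validate an input bundle.

    Either pass a ``directory`` holding the standard file names, or the
    individual paths.  Optional files (conservation, fasta, tags, tissues)
    are loaded when present.
    """
    paths = {
        "probesets": probesets, "transcripts": transcripts, "symbols": symbols,
        "annotation": annotation, "expr": expr, "tissues": tissues,
        "conservation": conservation, "fasta": fasta, "tags": tags,
    }
    if directory is not None:
        d = Path(directory)
        for key, fname in BUNDLE_FILES.items():
            if paths.get(key) is None and (d / fname).exists():
                paths[key] = d / fname
    for key in ("probesets", "transcripts", "symbols", "annotation", "expr"):
        if paths[key] is None:
            raise ValidationError(f"missing required input: {key}")

    ps = read_probesets_bed(paths["probesets"])
    ts = read_transcripts_bed12(paths["transcripts"], paths["symbols"])
    ann = read_annotation_tsv(paths["annotation"])
    m = read_expression_tsv(paths["expr"], paths["tissues"])

    ps_ids = {p.id for p in ps}
    t_ids = {t.id for t in ts}
    bad_ps = sorted(pid for pid, _ in ann.items() if pid not in ps_ids)
    if bad_ps:
        raise ValidationError(
            f"{paths['annotation']}: {len(bad_ps)} annotation probe sets unknown; "
            f"first offenders: {bad_ps[:10]}"
        )
    bad_t = sorted(
        tid for _, tids in ann.items() for tid in tids if tid not in t_ids
    )
    if bad_t:
        raise ValidationError(
            f"{paths['annotation']}: {len(bad_t)} annotated transcript ids unknown; "
            f"first offenders: {bad_t[:10]}"
        )

    return InputBundle(
        probesets=ps,
        transcripts=ts,
        annotation=ann,
        expression=m,
        conservation=read_bedgraph(paths["conservation"]) if paths["conservation"] else None,
        sequences=read_fasta(paths["fasta"]) if paths["fasta"] else None,
        tags=read_tags_bed(paths["tags"]) if paths["tags"] else None,
    )


def write_pools_bed(truth: TruthTable, utr_path, intergenic_path) -> None:
    write_bed6(((f"utr{i}", iv) for i, iv in enumerate(truth.utr_pool)), utr_path)
    write_bed6(
        ((f"ig{i}", iv) for i, iv in enumerate(truth.intergenic_pool)), intergenic_path
    )


def write_truth_tsv(truth: TruthTable, path) -> None:
    cols = [
        "gene_symbol", "transcript_id", "primary_id", "has_extension",
        "extended_id", "decoy_id", "ext_chrom", "ext_start", "ext_end",
        "strand", "planted_correlation", "low_primary", "has_tag", "motif_planted",
    ]
    rows = []
    for g in truth.genes:
        r = g.extension_region
        rows.append({
            "gene_symbol": g.gene_symbol,
            "transcript_id": g.transcript_id,
            "primary_id": g.primary_id,
            "has_extension": int(g.has_extension),
            "extended_id": g.extended_id or "",
            "decoy_id": g.decoy_id or "",
            "ext_chrom": r.chrom if r else "",
            "ext_start": r.start if r else "",
            "ext_end": r.end if r else "",
            "strand": g.span.strand,
            "planted_correlation": g.planted_correlation if g.planted_correlation is not None else "",
            "low_primary": int(g.low_primary),
            "has_tag": int(g.has_tag),
            "motif_planted": int(g.motif_planted),
        })
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write every bundle file (plus pools and truth) into ``outdir``."""
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    write_probesets_bed(bundle.probesets, d / "probesets.bed")
    write_transcripts_bed12(bundle.transcripts, d / "transcripts.bed12", d / "symbols.tsv")
    write_annotation_tsv(bundle.annotation, d / "annotation.tsv")
    write_expression_tsv(bundle.expression, d / "expr.tsv", d / "tissues.tsv")
    write_bedgraph(bundle.conservation, d / "cons.bedGraph")
    write_fasta(bundle.sequences, d / "genome.fa")
    write_bed6(((f"tag{i}", iv) for i, iv in enumerate(bundle.tags)), d / "tags.bed")
    write_pools_bed(bundle.truth, d / "utr_pool.bed", d / "intergenic_pool.bed")
    write_truth_tsv(bundle.truth, d / "truth.tsv")
    return {name: d / fname for name, fname in BUNDLE_FILES.items()}


def _format_pair(pair: ProbeSetPair) -> dict:
    return {
        "gene_symbol": pair.gene_symbol,
        "transcript_id": pair.transcript_id,
        "primary_probeset": pair.primary_id,
        "extended_probeset": pair.extended_id,
        "pearson_r": "" if pair.pearson_r is None else f"{pair.pearson_r:.6f}",
        "distance_bp": pair.distance,
        "ensembl_supported": "",
        "netaffx_supported": "",
    }


def write_predictions(report: PipelineReport, path, stages_path=None) -> None:
    """Prediction TSV (deterministic row order, r at 6 decimals) + stage counts."""
    rows = sorted(
        (_format_pair(p) for p in report.predictions),
        key=lambda r: (r["gene_symbol"], r["transcript_id"]),
    )
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, sep="\t", index=False)
    if stages_path is None:
        stages_path = Path(str(path) + ".stages.tsv")
    with open(stages_path, "w") as fh:
        fh.write("stage\tcount\n")
        for stage, count in report.stages:
            fh.write(f"{stage}\t{count}\n")


def write_pairs_tsv(pairs: Sequence[ProbeSetPair], path) -> None:
    rows = [_format_pair(p) for p in pairs]
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, parameters: Mapping, seed: Optional[int], inputs: Mapping[str, object]) -> None:
    """Machine-readable record of a run: parameters, seed, input checksums."""
    manifest = {
        "parameters": {k: v for k, v in parameters.items()},
        "seed": seed,
        "inputs": {
            str(name): {"path": str(p), "sha256": sha256_of(p)}
            for name, p in inputs.items()
            if p is not None and Path(str(p)).is_file()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
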