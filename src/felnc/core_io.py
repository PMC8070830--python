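"""Readers/writers and core genomic types for the lncRNA pipeline.

Internal coordinates are 0-based half-open throughout; on-disk GTF is
1-based inclusive. Transcript sequences are handled RNA-sense (``U``)
internally; FASTA input may use ``T``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "SampleDesign",
    "ExpressionMatrix",
    "GTFParseError",
    "ValidationError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "extract_transcript_sequence",
    "compute_fpkm",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_design_tsv",
    "write_design_tsv",
]


class GTFParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


class ValidationError(ValueError):
    """Raised when a genomic object violates its structural invariants."""


_RNA_COMPLEMENT = str.maketrans("ACGUacgu", "UGCAugca")
_DNA_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement; alphabet (DNA vs RNA) inferred from content."""
    table = _RNA_COMPLEMENT if ("U" in seq or "u" in seq) else _DNA_COMPLEMENT
    return seq.translate(table)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in nt with another interval on the same chromosome."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap(self, other: "GenomicInterval") -> int:
        """Genomic gap in nt between the two intervals (0 if they overlap)."""
        if self.chrom != other.chrom:
            raise ValidationError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript, the unit of the pipeline."""

    transcript_id: str
    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.span.chrom or exon.strand != self.span.strand:
                raise ValidationError(
                    f"{self.transcript_id}: exon on mixed strand/chromosome"
                )
            if exon.start < self.span.start or exon.end > self.span.end:
                raise ValidationError(f"{self.transcript_id}: exon outside span")
            if prev_end is not None and exon.start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = exon.end

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def exonic_length(self) -> int:
        return sum(e.length() for e in self.exons)


@dataclass(frozen=True)
class SampleDesign:
    """One library of the 2 tissue x 2 iron x replicate factorial."""

    sample_id: str
    tissue: str
    iron: str
    replicate: int

    def __post_init__(self) -> None:
        if self.tissue not in ("shoot", "root"):
            raise ValidationError(f"unknown tissue {self.tissue!r}")
        if self.iron not in ("sufficient", "deficient"):
            raise ValidationError(f"unknown iron condition {self.iron!r}")
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")


@dataclass
class ExpressionMatrix:
    """Transcript x sample abundances with factorial metadata.

    ``values`` is a DataFrame indexed by transcript_id with one column per
    sample_id, in the order of ``samples``. ``unit`` is ``count`` or ``FPKM``.
    """

    values: pd.DataFrame
    samples: list[SampleDesign]
    unit: str = "count"

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != ids:
            raise ValidationError("matrix columns do not match sample design")
        if len(set((s.tissue, s.iron, s.replicate) for s in self.samples)) != len(ids):
            raise ValidationError("duplicate (tissue, iron, replicate) in design")
        if (self.values.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.unit not in ("count", "FPKM"):
            raise ValidationError(f"unknown unit {self.unit!r}")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    def subset_samples(self, keep: Iterable[SampleDesign]) -> "ExpressionMatrix":
        keep = list(keep)
        return ExpressionMatrix(
            self.values[[s.sample_id for s in keep]], keep, self.unit
        )


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    Only ``exon`` features are used; they must carry ``transcript_id`` and
    ``gene_id`` attributes. On-disk 1-based inclusive coordinates are
    converted to internal 0-based half-open ones.
    """
    per_transcript: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GTFParseError(f"line {lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ValidationError(f"line {lineno}: exon end < start")
            attr = dict(_ATTR_RE.findall(attrs))
            if "transcript_id" not in attr or "gene_id" not in attr:
                raise GTFParseError(
                    f"line {lineno}: exon lacks transcript_id/gene_id attributes"
                )
            tid = attr["transcript_id"]
            exon = GenomicInterval(chrom, start1 - 1, end1, strand)
            rec = per_transcript.get(tid)
            if rec is None:
                per_transcript[tid] = {
                    "gene_id": attr["gene_id"],
                    "biotype": attr.get("biotype", "unknown"),
                    "exons": [exon],
                }
                order.append(tid)
            else:
                rec["exons"].append(exon)

    models: list[TranscriptModel] = []
    for tid in order:
        rec = per_transcript[tid]
        exons = sorted(rec["exons"], key=lambda e: e.start)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"transcript {tid}: exons on mixed strands or chromosomes"
            )
        span = GenomicInterval(
            exons[0].chrom, exons[0].start, exons[-1].end, exons[0].strand
        )
        models.append(
            TranscriptModel(tid, rec["gene_id"], span, exons, rec["biotype"])
        )
    return models


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    extra_attrs: Mapping[str, Mapping[str, str]] | None = None,
) -> None:
    """Write exon lines, 1-based inclusive, sorted by (chrom, start, id).

    ``extra_attrs`` optionally maps transcript_id -> {attr: value} appended
    to each exon line (e.g. a ``lncRNA_class`` annotation).
    """
    ordered = sorted(
        transcripts, key=lambda t: (t.chrom, t.span.start, t.transcript_id)
    )
    with open(path, "w") as fh:
        for t in ordered:
            extras = dict(extra_attrs.get(t.transcript_id, {})) if extra_attrs else {}
            for exon in t.exons:
                attr = (
                    f'transcript_id "{t.transcript_id}"; gene_id "{t.gene_id}"; '
                    f'biotype "{t.biotype}";'
                )
                for k, v in extras.items():
                    attr += f' {k} "{v}";'
                fh.write(
                    f"{exon.chrom}\tfelnc\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{exon.strand}\t.\t{attr}\n"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an uppercase {name: sequence} map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def extract_transcript_sequence(
    t: TranscriptModel, genome: Mapping[str, str]
) -> str:
    """Spliced transcript sequence, 5'->3' in transcript orientation, RNA-sense."""
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom!r} absent from genome")
    chrom_seq = genome[t.chrom]
    parts = []
    for exon in t.exons:
        if exon.end > len(chrom_seq):
            raise IndexError(
                f"{t.transcript_id}: exon {exon.start}-{exon.end} beyond end of "
                f"{t.chrom} (length {len(chrom_seq)})"
            )
        parts.append(chrom_seq[exon.start : exon.end])
    seq = "".join(parts).upper()
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq.replace("T", "U")


# ---------------------------------------------------------------------------
# FPKM and tabular I/O

def compute_fpkm(
    counts: ExpressionMatrix, transcripts: Iterable[TranscriptModel]
) -> ExpressionMatrix:
    """FPKM_ij = count_ij * 1e9 / (exonic_length_i * N_j).

    The per-sample library size N_j is the column sum of the count matrix.
    """
    if counts.unit != "count":
        raise ValidationError("compute_fpkm expects a count matrix")
    lengths = {t.transcript_id: t.exonic_length for t in transcripts}
    missing = [tid for tid in counts.values.index if tid not in lengths]
    if missing:
        raise KeyError(f"no transcript model for {missing[0]!r}")
    lens = np.array([lengths[tid] for tid in counts.values.index], dtype=float)
    libsize = counts.values.sum(axis=0).to_numpy(dtype=float)
    if (libsize <= 0).any():
        bad = counts.values.columns[np.flatnonzero(libsize <= 0)[0]]
        raise ValidationError(f"sample {bad!r} has zero library size")
    fpkm = counts.values.to_numpy(dtype=float) * 1e9 / (lens[:, None] * libsize[None, :])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.values.index, columns=counts.values.columns),
        counts.samples,
        unit="FPKM",
    )


def write_counts_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.6g")


def read_counts_tsv(path: str | Path, samples: list[SampleDesign]) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    unit = "count"
    return ExpressionMatrix(df[[s.sample_id for s in samples]], samples, unit)


def write_design_tsv(samples: Iterable[SampleDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttissue\tiron\treplicate\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.tissue}\t{s.iron}\t{s.replicate}\n")


def read_design_tsv(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleDesign(r.sample_id, r.tissue, r.iron, int(r.replicate))
        for r in df.itertuples()
    ]
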