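"""lncRNA identification and positional classification.

A transcript is called a lncRNA when it is at least 200 nt long and its
coding-potential score is negative. The score is a self-contained linear
function of longest-ORF features (length, coverage, start/stop integrity)
with fixed weights, keeping the classical sign convention: score < 0 means
noncoding. Surviving lncRNAs are then classified relative to coding
transcripts as antisense (opposite-strand exonic overlap), cis-sense
(same-strand exonic overlap, or a same-strand neighbor within 500 nt), or
intergenic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

from intervaltree import IntervalTree

from .core_io import TranscriptModel, extract_transcript_sequence

__all__ = [
    "CodingPotentialScore",
    "LncRNAClassLabel",
    "CodingIndex",
    "score_coding_potential",
    "identify_lncrnas",
    "classify_lncrna",
    "MIN_LNCRNA_LENGTH",
]

MIN_LNCRNA_LENGTH = 200  # nt; shorter transcripts are discarded outright
CIS_PROXIMITY_NT = 500  # max same-strand span gap for the cis-sense call

# coding-potential score weights and centering constants
_W_LEN = 2.0
_W_COV = 3.0
_W_INT = 0.5
_REF_ORF_LEN = 300.0  # nt at which the length term crosses zero
_REF_COV = 0.35  # ORF coverage at which the coverage term crosses zero

_STOPS = {"UAA", "UAG", "UGA"}


@dataclass(frozen=True)
class CodingPotentialScore:
    """Longest-ORF features and the signed coding-potential score."""

    transcript_id: str
    score: float
    orf_length: int
    orf_coverage: float
    orf_integrity: float  # 0 = no ORF, 0.5 = start only, 1 = start and stop

    @property
    def is_coding(self) -> bool:
        # ties at exactly 0 are assigned to the coding side (conservative
        # lncRNA call: lncRNAs require strictly negative scores)
        return self.score >= 0.0


@dataclass(frozen=True)
class LncRNAClassLabel:
    label: str  # intergenic | cis_sense | antisense
    partner_gene_id: str | None
    partner_transcript_id: str | None
    distance: int  # nt span gap to the partner; 0 if overlapping
    overlap_nt: int  # exonic overlap with the partner
    evidence: str | None  # for cis_sense: "overlap" or "proximal"

    def __post_init__(self) -> None:
        if (self.label == "intergenic") != (self.partner_gene_id is None):
            raise ValueError("intergenic iff partner is none")


def _longest_orf(seq: str) -> tuple[int, float]:
    """Longest ORF over the three forward frames.

    Returns (orf_length_nt, integrity). An ORF starts at an AUG; if an
    in-frame stop follows, the stop codon is included in the length and
    integrity is 1; an AUG running off the 3' end counts complete codons
    only, integrity 0.5. No AUG anywhere gives (0, 0).
    """
    best_len, best_int = 0, 0.0
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if start is None:
                if codon == "AUG":
                    start = i
            elif codon in _STOPS:
                length = i + 3 - start
                if length > best_len:
                    best_len, best_int = length, 1.0
                start = None
            i += 3
        if start is not None:
            length = i - start  # complete codons only, no stop found
            if length > best_len:
                best_len, best_int = length, 0.5
    return best_len, best_int


def score_coding_potential(seq: str, transcript_id: str = "") -> CodingPotentialScore:
    """Score a sense-oriented RNA sequence for protein-coding potential.

    score = w_L*(log10(orf_length+1) - log10(300))
          + w_C*(orf_coverage - 0.35) + w_I*(orf_integrity - 1)
    with w_L = 2, w_C = 3, w_I = 0.5. Strictly increasing in ORF length
    and coverage; negative scores are called noncoding.
    """
    if not seq:
        raise ValueError("empty sequence")
    invalid = set(seq) - set("ACGU")
    if invalid:
        raise ValueError(f"invalid RNA character(s): {sorted(invalid)}")
    orf_len, integrity = _longest_orf(seq)
    coverage = orf_len / len(seq)
    score = (
        _W_LEN * (math.log10(orf_len + 1) - math.log10(_REF_ORF_LEN))
        + _W_COV * (coverage - _REF_COV)
        + _W_INT * (integrity - 1.0)
    )
    return CodingPotentialScore(transcript_id, score, orf_len, coverage, integrity)


class IdentifyResult(NamedTuple):
    lncrnas: list[TranscriptModel]
    mrnas: list[TranscriptModel]
    scores: dict[str, CodingPotentialScore]


def identify_lncrnas(
    transcripts: Iterable[TranscriptModel],
    genome: Mapping[str, str],
    min_length: int = MIN_LNCRNA_LENGTH,
) -> IdentifyResult:
    """Partition transcripts of >= ``min_length`` nt into lncRNAs and mRNAs.

    Shorter transcripts are discarded. Each survivor lands in exactly one
    list by the sign of its coding-potential score; returned models carry
    biotype ``lncRNA`` or ``coding``.
    """
    lncs: list[TranscriptModel] = []
    mrnas: list[TranscriptModel] = []
    scores: dict[str, CodingPotentialScore] = {}
    for t in transcripts:
        if t.exonic_length < min_length:
            continue
        seq = extract_transcript_sequence(t, genome)
        cp = score_coding_potential(seq, t.transcript_id)
        scores[t.transcript_id] = cp
        if cp.is_coding:
            t.biotype = "coding"
            mrnas.append(t)
        else:
            t.biotype = "lncRNA"
            lncs.append(t)
    return IdentifyResult(lncs, mrnas, scores)


class CodingIndex:
    """Exon interval trees plus per-strand span lists over coding transcripts."""

    def __init__(self, coding: Iterable[TranscriptModel]):
        self.transcripts = [t for t in coding]
        for t in self.transcripts:
            if t.biotype != "coding":
                raise ValueError(f"{t.transcript_id}: index accepts coding only")
        self._exon_trees: dict[str, IntervalTree] = {}
        self._spans: dict[tuple[str, str], list[TranscriptModel]] = {}
        for t in self.transcripts:
            tree = self._exon_trees.setdefault(t.chrom, IntervalTree())
            for exon in t.exons:
                tree.addi(exon.start, exon.end, t)
            self._spans.setdefault((t.chrom, t.strand), []).append(t)

    def exon_overlappers(self, lnc: TranscriptModel) -> dict[str, tuple[TranscriptModel, int]]:
        """Coding transcripts whose exons overlap lnc exons, with overlap nt."""
        tree = self._exon_trees.get(lnc.chrom)
        if tree is None:
            return {}
        totals: dict[str, tuple[TranscriptModel, int]] = {}
        for exon in lnc.exons:
            for iv in tree.overlap(exon.start, exon.end):
                partner: TranscriptModel = iv.data
                nt = min(exon.end, iv.end) - max(exon.start, iv.begin)
                prev = totals.get(partner.transcript_id)
                totals[partner.transcript_id] = (partner, (prev[1] if prev else 0) + nt)
        return totals

    def same_strand_spans(self, lnc: TranscriptModel) -> list[TranscriptModel]:
        return self._spans.get((lnc.chrom, lnc.strand), [])


def classify_lncrna(
    lnc: TranscriptModel,
    index: CodingIndex,
    max_gap: int = CIS_PROXIMITY_NT,
) -> LncRNAClassLabel:
    """Positional class of a lncRNA relative to coding transcripts.

    Priority: (1) same-strand exonic overlap -> cis_sense (overlap);
    (2) opposite-strand exonic overlap -> antisense; (3) nearest same-strand
    coding span within 500 nt -> cis_sense (proximal); (4) intergenic.
    Partners maximize overlap (1-2) or minimize distance (3); ties break by
    lexicographic (gene_id, transcript_id).
    """
    overlappers = index.exon_overlappers(lnc)
    same = [(t, nt) for t, nt in overlappers.values() if t.strand == lnc.strand]
    opp = [(t, nt) for t, nt in overlappers.values() if t.strand != lnc.strand]

    def _best_overlap(cands: list[tuple[TranscriptModel, int]]) -> tuple[TranscriptModel, int]:
        return min(cands, key=lambda p: (-p[1], p[0].gene_id, p[0].transcript_id))

    if same:
        partner, nt = _best_overlap(same)
        return LncRNAClassLabel(
            "cis_sense", partner.gene_id, partner.transcript_id,
            lnc.span.gap(partner.span), nt, "overlap",
        )
    if opp:
        partner, nt = _best_overlap(opp)
        return LncRNAClassLabel(
            "antisense", partner.gene_id, partner.transcript_id,
            lnc.span.gap(partner.span), nt, None,
        )
    best: tuple[int, str, str, TranscriptModel] | None = None
    for t in index.same_strand_spans(lnc):
        if t.transcript_id == lnc.transcript_id:
            continue
        gap = lnc.span.gap(t.span)
        key = (gap, t.gene_id, t.transcript_id)
        if gap <= max_gap and (best is None or key < best[:3]):
            best = (gap, t.gene_id, t.transcript_id, t)
    if best is not None:
        gap, _, _, partner = best
        return LncRNAClassLabel(
            "cis_sense", partner.gene_id, partner.transcript_id, gap, 0, "proximal"
        )
    return LncRNAClassLabel("intergenic", None, None, 0, 0, None)
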