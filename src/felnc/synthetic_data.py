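"""Self-contained synthetic study generator with planted ground truth.

Emulates the study design the pipeline was built for: a small
multi-chromosome genome carrying ORF-bearing coding genes and ORF-less
lncRNAs of each positional class (intergenic, cis-sense at 100-500 nt on
the same strand, antisense overlapping a coding exon), decoy transcripts
(sub-200 nt and ORF-bearing), pre-miRNA loci planted inside lncRNAs, eTM
motifs, reverse-complement cassettes creating guaranteed cis/trans duplex
partners, and negative-binomial counts for the 2 tissue x 2 iron x 3
replicate factorial with planted fold changes realizing expression classes
I-V. Every planted feature is recorded in a truth table, and every
artifact is deterministic under the configured seed.

lncRNA sequences are generated AUG-free in every frame (so their
coding-potential scores are negative by construction) and coding genes get
full-length ORFs; this makes catalog recovery on generated data exact
rather than probabilistic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    ExpressionMatrix,
    GenomicInterval,
    SampleDesign,
    TranscriptModel,
    write_counts_tsv,
    write_design_tsv,
    write_fasta,
    write_gtf,
)
from .interactions import pairing_free_energy
from .mirna_links import PreMirnaLocus, write_mirna_tsv

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "simulate_annotation",
    "simulate_counts",
    "simulate_study",
    "simulate_matrix_study",
    "write_study",
]

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

_DNA_RC = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_DNA_RC)[::-1]


def _dna(seq_rna: str) -> str:
    return seq_rna.replace("U", "T")


@dataclass
class SimConfig:
    """Generation parameters; defaults are the package's study conditions."""

    seed: int = 42
    n_chroms: int = 3
    chrom_len: int = 400_000
    n_coding: int = 40
    n_lnc_intergenic: int = 20
    n_lnc_cis: int = 10
    n_lnc_antisense: int = 10
    n_short_decoys: int = 5
    n_orf_decoys: int = 5
    n_precursor_plants: int = 2
    n_etm_plants: int = 2
    n_cis_pairs: int = 3
    n_trans_pairs: int = 4
    n_target_site_plants: int = 3
    n_replicates: int = 3
    # log-normal background abundance (natural-log scale) and planted levels.
    # The background spans low- to high-expression transcripts as in real
    # libraries; up-regulated plants start moderate, down-regulated plants
    # (classes I/III: "highly expressed, down under deficiency") start high,
    # which also keeps the planted mass from distorting FPKM normalization.
    baseline_fpkm_log_mean: float = 3.0
    baseline_fpkm_log_sigma: float = 1.5
    planted_baseline_fpkm: float = 40.0
    planted_down_baseline_fpkm: float = 500.0
    planted_log2fc: float = 3.0
    nb_dispersion: float = 0.05
    depth: float = 3e6
    de_lnc_per_class: dict = field(
        default_factory=lambda: {"I": 2, "II": 3, "III": 2, "IV": 2, "V": 3}
    )
    de_mrna_per_class: dict = field(
        default_factory=lambda: {"I": 2, "II": 3, "III": 2, "IV": 3, "V": 4}
    )

    def validate(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("negative-binomial dispersion must be >= 0")
        n_de_lnc = sum(self.de_lnc_per_class.values())
        if n_de_lnc > self.n_lnc_intergenic:
            raise ValueError("more DE-lncRNA plants than intergenic lncRNAs")
        n_hosts = (self.n_trans_pairs + self.n_etm_plants + self.n_cis_pairs
                   + self.n_precursor_plants)
        if n_hosts > n_de_lnc:
            raise ValueError("motif plants exceed the DE-lncRNA budget")
        if self.n_cis_pairs + self.n_lnc_cis + self.n_lnc_antisense > self.n_coding:
            raise ValueError("not enough coding genes for the paired layouts")


@dataclass
class SimulatedStudy:
    config: SimConfig
    transcripts: list[TranscriptModel]
    genome: dict[str, str]
    mirnas: list[PreMirnaLocus]
    mature_mirna: str  # RNA alphabet
    truth: pd.DataFrame
    go_annotation: dict[str, list[str]]
    go_terms: dict[str, tuple[str, str]]
    fe_genes: list[str]
    counts: ExpressionMatrix | None = None
    samples: list[SampleDesign] | None = None


# ---------------------------------------------------------------------------
# sequence design helpers

def _rand_seq(rng: np.random.Generator, n: int, banned: tuple[str, ...] = ()) -> str:
    """Random DNA avoiding every banned 3-mer, including across growth."""
    if not banned:
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
    out: list[str] = []
    for _ in range(n):
        for b in rng.permutation(list("ACGT")):
            out.append(b)
            tail = "".join(out[-3:])
            if any(tail == m for m in banned if len(out) >= 3):
                out.pop()
                continue
            break
    return "".join(out)


def _design_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons)
    )
    return "ATG" + body + "TAA"


def _design_cassette(rng: np.random.Generator, n: int, min_abs_dg: float) -> str:
    """CAT/ATG-free cassette whose perfect duplex clears ``min_abs_dg``."""
    for _ in range(200):
        c = _rand_seq(rng, n, banned=("ATG", "CAT"))
        e = pairing_free_energy(c.replace("T", "U"), _rc(c).replace("T", "U"))
        if e.dG <= -min_abs_dg:
            return c
    raise RuntimeError("could not design a cassette of the requested stability")


def _design_mirna(rng: np.random.Generator, length: int = 21) -> str:
    """Mature miRNA (DNA letters) free of ATG and CAT, moderately GC-rich."""
    for _ in range(200):
        m = _rand_seq(rng, length, banned=("ATG", "CAT"))
        gc = sum(b in "GC" for b in m) / length
        if 0.45 <= gc <= 0.65:
            return m
    raise RuntimeError("could not design a mature miRNA")


def _etm_site(mirna_dna: str, bulge: str = "CCC") -> str:
    """Mimic site: complement of the miRNA with a 3-nt bulge between the
    bases opposite miRNA positions 10 and 11 (5' numbering)."""
    m = mirna_dna
    return _rc(m[10:]) + bulge + _rc(m[:10])


def _exonic_to_genomic(t: TranscriptModel, offset: int) -> int:
    """Genomic coordinate of a 0-based offset into the spliced sense sequence."""
    if t.strand == "-":
        offset = t.exonic_length - 1 - offset
    for exon in t.exons:
        if offset < exon.length():
            return exon.start + offset
        offset -= exon.length()
    raise IndexError("offset beyond exonic length")


# ---------------------------------------------------------------------------
# annotation generation

class _Layout:
    """Sequential round-robin placement of isolated units on chromosomes."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.cursors = {f"chr{i + 1}": 2000 for i in range(cfg.n_chroms)}
        self._next = 0

    def place(self, extent: int) -> tuple[str, int]:
        chroms = sorted(self.cursors)
        for _ in range(len(chroms)):
            chrom = chroms[self._next % len(chroms)]
            self._next += 1
            start = self.cursors[chrom]
            if start + extent + 2000 <= self.cfg.chrom_len:
                self.cursors[chrom] = start + extent + int(self.rng.integers(2500, 4000))
                return chrom, start
        raise RuntimeError(
            "placement error: chromosomes too short for the configured layout"
        )


def _assign_de_classes(per_class: Mapping[str, int], ids: list[str]) -> dict[str, str]:
    expanded: list[str] = []
    for cls in sorted(per_class):
        expanded.extend([cls] * per_class[cls])
    if len(expanded) > len(ids):
        raise ValueError("more DE plants than available transcripts")
    return dict(zip(ids, expanded))


_CLASS_STATUS = {
    "I": ("ns", "down"),
    "II": ("ns", "up"),
    "III": ("down", "ns"),
    "IV": ("up", "ns"),
    "V": ("up", "up"),
    "none": ("ns", "ns"),
}


def simulate_annotation(cfg: SimConfig) -> SimulatedStudy:
    """Generate genome, transcript models, miRNA loci and the truth table."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    layout = _Layout(cfg, rng)

    mirna_dna = _design_mirna(rng)
    mature_rna = mirna_dna.replace("T", "U")

    transcripts: list[TranscriptModel] = []
    designed: dict[str, str] = {}  # transcript_id -> designed sense DNA
    truth_rows: list[dict] = []
    mirnas: list[PreMirnaLocus] = []
    # planted motif positions to resolve after models exist
    pre_plants: list[tuple[str, int]] = []  # (lnc_id, exonic offset of mature)

    n_de_lnc = sum(cfg.de_lnc_per_class.values())
    lnc_counter = gene_counter = 0

    def _new_lnc_id() -> str:
        nonlocal lnc_counter
        lnc_counter += 1
        return f"LNC{lnc_counter:04d}"

    def _new_gene_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"G{gene_counter:04d}"

    def _gene_seq(u3_inserts: list[str]) -> str:
        u5 = _rand_seq(rng, 60, banned=("CAT",))
        orf = _design_orf(rng, int(rng.integers(180, 230)))
        if not u3_inserts:
            # one piece: a CAT must not form across segment junctions, since
            # antisense lncRNAs read plain-gene UTRs in reverse complement
            return u5 + orf + _rand_seq(rng, 100, banned=("CAT",))
        u3 = _rand_seq(rng, 40, banned=("CAT",))
        for ins in u3_inserts:
            u3 += "CC" + ins + "CC" + _rand_seq(rng, 20, banned=("CAT",))
        u3 += _rand_seq(rng, 60, banned=("CAT",))
        return u5 + orf + u3

    def _lnc_seq(total: int, inserts: list[str]) -> tuple[str, list[int]]:
        """AUG-free lncRNA sense DNA with inserts; returns insert offsets."""
        for ins in inserts:
            assert "ATG" not in ins, "insert would break the AUG-free design"
        fill = total - sum(len(i) + 4 for i in inserts)
        n_parts = len(inserts) + 1
        part_len = max(20, fill // n_parts)
        seq = _rand_seq(rng, part_len, banned=("ATG",))
        offsets: list[int] = []
        for ins in inserts:
            seq += "CC"
            offsets.append(len(seq))
            seq += ins + "CC" + _rand_seq(rng, part_len, banned=("ATG",))
        if len(seq) < total:
            seq += _rand_seq(rng, total - len(seq), banned=("ATG",))
        return seq, offsets

    def _add_transcript(
        tid: str, gene_id: str, chrom: str, start: int, strand: str,
        seq: str, n_exons: int = 1, intron_len: int = 300,
    ) -> TranscriptModel:
        if n_exons == 2:
            half = len(seq) // 2
            # exon coordinates follow the genomic (plus-strand) axis
            g_first, g_second = (
                (seq[:half], seq[half:]) if strand == "+" else (seq[half:], seq[:half])
            )
            e1 = GenomicInterval(chrom, start, start + len(g_first), strand)
            e2 = GenomicInterval(
                chrom, e1.end + intron_len, e1.end + intron_len + len(g_second), strand
            )
            span = GenomicInterval(chrom, e1.start, e2.end, strand)
            t = TranscriptModel(tid, gene_id, span, [e1, e2])
        else:
            span = GenomicInterval(chrom, start, start + len(seq), strand)
            t = TranscriptModel(tid, gene_id, span, [span])
        transcripts.append(t)
        designed[tid] = seq
        return t

    # ---- plan the DE-lncRNA roster over intergenic lncRNAs ----------------
    intergenic_ids = [f"LNC{i + 1:04d}" for i in range(cfg.n_lnc_intergenic)]
    trans_lncs = intergenic_ids[: cfg.n_trans_pairs]
    etm_lncs = intergenic_ids[cfg.n_trans_pairs : cfg.n_trans_pairs + cfg.n_etm_plants]
    cis_pair_lncs = intergenic_ids[
        cfg.n_trans_pairs + cfg.n_etm_plants :
        cfg.n_trans_pairs + cfg.n_etm_plants + cfg.n_cis_pairs
    ]
    n_hosts = cfg.n_trans_pairs + cfg.n_etm_plants + cfg.n_cis_pairs
    # precursor hosts are also drawn from the DE roster: the precursor scan
    # downstream runs over differentially expressed lncRNAs
    precursor_lncs = intergenic_ids[n_hosts : n_hosts + cfg.n_precursor_plants]
    de_lnc_ids = intergenic_ids[:n_de_lnc]
    lnc_class = _assign_de_classes(cfg.de_lnc_per_class, de_lnc_ids)

    # cassettes shared between each planted pair
    trans_cassettes = [_design_cassette(rng, 30, 55.0) for _ in trans_lncs]
    cis_cassettes = [_design_cassette(rng, 60, 110.0) for _ in cis_pair_lncs]
    etm_insert = _etm_site(mirna_dna)

    # ---- intergenic lncRNAs (plants live here; planted hosts stay '+') ----
    trans_insert_of: dict[str, str] = dict(zip(trans_lncs, trans_cassettes))
    for i, lnc_id in enumerate(intergenic_ids):
        _new_lnc_id()
        inserts: list[str] = []
        if lnc_id in trans_insert_of:
            inserts.append(_rc(trans_insert_of[lnc_id]))
        if lnc_id in etm_lncs:
            inserts.append(etm_insert)
        if lnc_id in cis_pair_lncs:
            j = cis_pair_lncs.index(lnc_id)
            inserts.append(_rc(cis_cassettes[j]))
        if lnc_id in precursor_lncs:
            inserts.append(mirna_dna)
        total = int(rng.integers(400, 480))
        seq, offsets = _lnc_seq(total, inserts)
        planted = bool(inserts)
        strand = "+" if planted else ("+" if rng.integers(2) == 0 else "-")
        n_exons = 1 if planted else (2 if rng.integers(4) == 0 else 1)
        if lnc_id in cis_pair_lncs:
            # gene placed 8 kb downstream of the lncRNA on the same chromosome
            j = cis_pair_lncs.index(lnc_id)
            gid = _new_gene_id()
            gseq = _gene_seq([cis_cassettes[j]])
            chrom, start = layout.place(len(seq) + 8000 + len(gseq))
            _add_transcript(lnc_id, lnc_id, chrom, start, strand, seq, n_exons)
            gstart = start + len(seq) + 8000
            gstrand = "+" if rng.integers(2) == 0 else "-"
            _add_transcript(f"T{gid}", gid, chrom, gstart, gstrand, gseq)
            truth_rows.append(
                {"transcript_id": f"T{gid}", "kind": "coding", "positional_class": "",
                 "partner": "", "de_class": "none", "trans_partner": "",
                 "cis_partner": lnc_id, "precursor_mirna": "", "etm": False}
            )
            cis_partner_gene = gid
        else:
            chrom, start = layout.place(len(seq) + (300 if n_exons == 2 else 0))
            _add_transcript(lnc_id, lnc_id, chrom, start, strand, seq, n_exons)
            cis_partner_gene = ""
        if lnc_id in precursor_lncs:
            pre_plants.append((lnc_id, offsets[-1]))
        truth_rows.append(
            {"transcript_id": lnc_id, "kind": "lncRNA",
             "positional_class": "intergenic", "partner": "",
             "de_class": lnc_class.get(lnc_id, "none"),
             "trans_partner": "", "cis_partner": cis_partner_gene,
             "precursor_mirna": ("pre-simR1-" + lnc_id) if lnc_id in precursor_lncs else "",
             "etm": lnc_id in etm_lncs}
        )

    # ---- cis-sense lncRNAs: same strand, 100-500 nt from their gene -------
    for _ in range(cfg.n_lnc_cis):
        lnc_id = _new_lnc_id()
        gid = _new_gene_id()
        gseq = _gene_seq([])
        total = int(rng.integers(400, 480))
        seq, _ = _lnc_seq(total, [])
        gap = int(rng.integers(100, 501))
        chrom, start = layout.place(len(gseq) + gap + len(seq))
        strand = "+" if rng.integers(2) == 0 else "-"
        _add_transcript(f"T{gid}", gid, chrom, start, strand, gseq)
        _add_transcript(lnc_id, lnc_id, chrom, start + len(gseq) + gap, strand, seq)
        truth_rows.append(
            {"transcript_id": f"T{gid}", "kind": "coding", "positional_class": "",
             "partner": "", "de_class": "none", "trans_partner": "",
             "cis_partner": "", "precursor_mirna": "", "etm": False}
        )
        truth_rows.append(
            {"transcript_id": lnc_id, "kind": "lncRNA",
             "positional_class": "cis_sense", "partner": gid, "de_class": "none",
             "trans_partner": "", "cis_partner": "", "precursor_mirna": "",
             "etm": False}
        )

    # ---- antisense lncRNAs: opposite strand, overlapping the gene 3'UTR ---
    for _ in range(cfg.n_lnc_antisense):
        lnc_id = _new_lnc_id()
        gid = _new_gene_id()
        gseq = _gene_seq([])
        total = int(rng.integers(400, 480))
        overlap = 80
        chrom, start = layout.place(len(gseq) + total - overlap)
        gstrand = "+" if rng.integers(2) == 0 else "-"
        gene = _add_transcript(f"T{gid}", gid, chrom, start, gstrand, gseq)
        lstrand = "-" if gstrand == "+" else "+"
        if gstrand == "+":
            lstart = gene.span.end - overlap
        else:
            lstart = gene.span.start + overlap - total
        # the designed lnc sequence covers the non-overlap part only; the
        # overlapping 80 nt come from the gene UTR (CAT-free, hence AUG-free
        # on the antisense strand); a patch pass below fixes junction AUGs
        seq, _ = _lnc_seq(total - overlap, [])
        span = GenomicInterval(chrom, lstart, lstart + total, lstrand)
        t = TranscriptModel(lnc_id, lnc_id, span, [span])
        transcripts.append(t)
        designed[lnc_id] = seq  # partial; resolved during genome assembly
        truth_rows.append(
            {"transcript_id": f"T{gid}", "kind": "coding", "positional_class": "",
             "partner": "", "de_class": "none", "trans_partner": "",
             "cis_partner": "", "precursor_mirna": "", "etm": False}
        )
        truth_rows.append(
            {"transcript_id": lnc_id, "kind": "lncRNA",
             "positional_class": "antisense", "partner": gid, "de_class": "none",
             "trans_partner": "", "cis_partner": "", "precursor_mirna": "",
             "etm": False}
        )

    # ---- remaining standalone coding genes --------------------------------
    n_placed_genes = cfg.n_cis_pairs + cfg.n_lnc_cis + cfg.n_lnc_antisense
    standalone_gids: list[str] = []
    target_gids: list[str] = []
    trans_gene_of: dict[str, str] = {}
    # planted miRNA target site: complement of the miRNA with one mismatch
    # opposite (non-seed) position 15, as natural sites carry — which also
    # keeps the site from doubling as a long perfect duplex in the trans scan
    target_site = list(_rc(mirna_dna))
    _b15 = mirna_dna[14]
    target_site[len(mirna_dna) - 15] = "C" if _b15 == "T" else "A"
    target_site = "".join(target_site)
    for i in range(cfg.n_coding - n_placed_genes):
        gid = _new_gene_id()
        inserts: list[str] = []
        if i < cfg.n_trans_pairs:
            inserts.append(trans_cassettes[i])
            trans_gene_of[trans_lncs[i]] = gid
        elif i < cfg.n_trans_pairs + cfg.n_target_site_plants:
            inserts.append(target_site)
            target_gids.append(gid)
        gseq = _gene_seq(inserts)
        chrom, start = layout.place(len(gseq))
        strand = "+" if rng.integers(2) == 0 else "-"
        _add_transcript(f"T{gid}", gid, chrom, start, strand, gseq)
        standalone_gids.append(gid)
        truth_rows.append(
            {"transcript_id": f"T{gid}", "kind": "coding", "positional_class": "",
             "partner": "", "de_class": "none",
             "trans_partner": trans_lncs[i] if i < cfg.n_trans_pairs else "",
             "cis_partner": "",
             "precursor_mirna": "",
             "etm": False}
        )

    # DE-mRNA roster: trans-pair genes first, then other genes; cis-pair
    # partner genes stay non-DE so their cassette never doubles as a trans edge
    trans_genes_list = [trans_gene_of[l] for l in trans_lncs]
    cis_pair_genes = {
        r["cis_partner"] for r in truth_rows
        if r["kind"] == "lncRNA" and r["cis_partner"]
    }
    all_gids_sorted = sorted(
        {t.gene_id for t in transcripts if t.transcript_id.startswith("TG")}
    )
    # miRNA-target-site hosts join the roster too: the target scan downstream
    # runs over differentially expressed mRNAs
    de_gene_ids = trans_genes_list + target_gids + [
        g for g in all_gids_sorted
        if g not in trans_genes_list and g not in target_gids
        and g not in cis_pair_genes
    ]
    de_gene_ids = de_gene_ids[: sum(cfg.de_mrna_per_class.values())]
    gene_class = _assign_de_classes(cfg.de_mrna_per_class, de_gene_ids)

    # ---- decoys ------------------------------------------------------------
    for i in range(cfg.n_short_decoys):
        tid = f"DECS{i + 1:03d}"
        seq, _ = _lnc_seq(int(rng.integers(150, 200)), [])
        chrom, start = layout.place(len(seq))
        _add_transcript(tid, tid, chrom, start, "+", seq)
        truth_rows.append(
            {"transcript_id": tid, "kind": "short_decoy", "positional_class": "",
             "partner": "", "de_class": "none", "trans_partner": "",
             "cis_partner": "", "precursor_mirna": "", "etm": False}
        )
    for i in range(cfg.n_orf_decoys):
        tid = f"DECO{i + 1:03d}"
        seq = _design_orf(rng, 160)
        chrom, start = layout.place(len(seq))
        _add_transcript(tid, tid, chrom, start, "+", seq)
        truth_rows.append(
            {"transcript_id": tid, "kind": "orf_decoy", "positional_class": "",
             "partner": "", "de_class": "none", "trans_partner": "",
             "cis_partner": "", "precursor_mirna": "", "etm": False}
        )

    # ---- genome assembly ---------------------------------------------------
    chrom_arrays = {
        f"chr{i + 1}": bytearray(
            _rand_seq(rng, cfg.chrom_len).encode()
        )
        for i in range(cfg.n_chroms)
    }

    antisense_ids = {
        r["transcript_id"] for r in truth_rows if r["positional_class"] == "antisense"
    }
    for t in transcripts:
        if t.transcript_id in antisense_ids:
            continue
        seq = designed[t.transcript_id]
        genomic = seq if t.strand == "+" else _rc(seq)
        pos = 0
        for exon in t.exons:
            piece = genomic[pos : pos + exon.length()]
            chrom_arrays[t.chrom][exon.start : exon.end] = piece.encode()
            pos += exon.length()
    # antisense lncRNAs: write the designed part onto the non-overlap region
    for t in transcripts:
        if t.transcript_id not in antisense_ids:
            continue
        seq = designed[t.transcript_id]  # lnc-sense, non-overlap part only
        if t.strand == "-":
            # partner gene is '+' and occupies the left of the lnc span
            region_start = t.span.start + 80
            chrom_arrays[t.chrom][region_start : t.span.end] = _rc(seq).encode()
        else:
            region_start = t.span.start
            chrom_arrays[t.chrom][region_start : region_start + len(seq)] = seq.encode()

    genome = {c: chrom_arrays[c].decode() for c in sorted(chrom_arrays)}

    # ---- patch pass: enforce AUG-free lncRNA (and decoy) sequences --------
    protected: list[tuple[str, int, int]] = [
        (t.chrom, t.span.start, t.span.end)
        for t in transcripts
        if t.transcript_id.startswith("TG")
    ]

    def _is_protected(chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos < e for c, s, e in protected)

    lnc_like = [
        t for t in transcripts
        if not t.transcript_id.startswith(("TG", "DECO"))
    ]
    for t in lnc_like:
        for _ in range(200):
            arr = chrom_arrays[t.chrom]
            sense = "".join(
                arr[e.start : e.end].decode() for e in t.exons
            )
            if t.strand == "-":
                sense = _rc(sense)
            idx = sense.find("ATG")
            if idx < 0:
                break
            for off in (idx + 2, idx + 1, idx):  # prefer patching the G
                gpos = _exonic_to_genomic(t, off)
                if not _is_protected(t.chrom, gpos):
                    base = "C" if t.strand == "+" else "G"
                    arr[gpos : gpos + 1] = base.encode()
                    break
            else:  # pragma: no cover - placement makes this unreachable
                raise RuntimeError(f"{t.transcript_id}: unpatchable AUG")
        else:  # pragma: no cover
            raise RuntimeError(f"{t.transcript_id}: AUG patching did not converge")
    genome = {c: chrom_arrays[c].decode() for c in sorted(chrom_arrays)}

    # ---- pre-miRNA loci -----------------------------------------------------
    by_id = {t.transcript_id: t for t in transcripts}
    for lnc_id, offset in pre_plants:
        t = by_id[lnc_id]
        g_a = _exonic_to_genomic(t, offset)
        g_b = _exonic_to_genomic(t, offset + len(mirna_dna) - 1)
        lo, hi = min(g_a, g_b), max(g_a, g_b) + 1
        margin = 30
        pre_start = max(t.span.start, lo - margin)
        pre_end = min(t.span.end, hi + margin)
        mirnas.append(
            PreMirnaLocus(
                "pre-simR1-" + lnc_id,
                GenomicInterval(t.chrom, pre_start, pre_end, t.strand),
                mature_rna,
            )
        )

    # ---- GO annotation, Fe gene list ---------------------------------------
    all_gene_ids = sorted(
        {t.gene_id for t in transcripts if t.transcript_id.startswith("TG")}
    )
    trans_genes = [trans_gene_of[l] for l in trans_lncs]
    cis_genes = [r["cis_partner"] for r in truth_rows if r["cis_partner"]
                 and r["kind"] == "lncRNA"]
    fe_genes = sorted(set(trans_genes + cis_genes))
    extra_fe = [g for g in all_gene_ids if g not in fe_genes][:3]
    fe_genes = sorted(fe_genes + extra_fe)

    go_terms: dict[str, tuple[str, str]] = {
        "GO:2000001": ("iron ion transport", "biological_process"),
        "GO:2000002": ("metal ion homeostasis", "biological_process"),
    }
    go_annotation: dict[str, list[str]] = {g: [] for g in all_gene_ids}
    # the planted iron term covers the trans-target genes plus one bystander,
    # so the trans-target gene set comes out strongly enriched for it
    iron_term_genes = sorted(set(trans_genes)) + extra_fe[:1]
    for g in iron_term_genes:
        go_annotation[g].append("GO:2000001")
    for i in range(10):
        term = f"GO:10000{i:02d}"
        go_terms[term] = (f"background process {i + 1}", "biological_process")
        members = rng.choice(all_gene_ids, size=8, replace=False)
        for g in members:
            go_annotation[g].append(term)
    go_terms["GO:3000001"] = ("nucleotide binding", "molecular_function")
    for g in all_gene_ids[::5]:
        go_annotation[g].append("GO:3000001")

    truth = pd.DataFrame(truth_rows).set_index("transcript_id")
    truth["mirna_target"] = False
    truth.loc[[f"T{g}" for g in target_gids], "mirna_target"] = True
    gene_tid = {g: f"T{g}" for g in all_gene_ids}
    for g, cls in gene_class.items():
        truth.loc[gene_tid[g], "de_class"] = cls
    shoots, roots = zip(
        *(_CLASS_STATUS.get(c, ("ns", "ns")) for c in truth["de_class"])
    )
    truth["de_shoot"] = shoots
    truth["de_root"] = roots

    return SimulatedStudy(
        cfg, transcripts, genome, mirnas, mature_rna, truth,
        go_annotation, go_terms, fe_genes,
    )


# ---------------------------------------------------------------------------
# count simulation

def _design_samples(n_replicates: int) -> list[SampleDesign]:
    samples = []
    for tissue in ("shoot", "root"):
        for iron in ("sufficient", "deficient"):
            for r in range(1, n_replicates + 1):
                samples.append(
                    SampleDesign(f"{tissue}_{iron[:3]}_{r}", tissue, iron, r)
                )
    return samples


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + phi * mu^2; Poisson at phi=0."""
    if phi == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def simulate_counts(
    cfg: SimConfig,
    transcripts: list[TranscriptModel],
    truth: pd.DataFrame,
    seed_offset: int = 1,
) -> tuple[ExpressionMatrix, list[SampleDesign]]:
    """Negative-binomial counts for the factorial design.

    Expected count = baseline_FPKM * 2^(planted shift) * exonic_length *
    depth / 1e9, where the shift applies in the (tissue, deficient) cells
    the truth table marks up (+log2fc) or down (-log2fc).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + seed_offset)
    samples = _design_samples(cfg.n_replicates)
    ids = [t.transcript_id for t in transcripts]
    lengths = np.array([t.exonic_length for t in transcripts], dtype=float)
    de_class = truth["de_class"].reindex(ids).fillna("none")
    background = rng.lognormal(
        cfg.baseline_fpkm_log_mean, cfg.baseline_fpkm_log_sigma, len(ids)
    )
    baseline = np.where(
        de_class.isin(["I", "III"]),
        cfg.planted_down_baseline_fpkm,
        np.where(de_class != "none", cfg.planted_baseline_fpkm, background),
    )
    shift = {"up": cfg.planted_log2fc, "down": -cfg.planted_log2fc, "ns": 0.0}
    de_shoot = truth["de_shoot"].reindex(ids).fillna("ns")
    de_root = truth["de_root"].reindex(ids).fillna("ns")
    cols = {}
    for s in samples:
        status = de_shoot if s.tissue == "shoot" else de_root
        delta = np.array([shift[x] for x in status])
        fpkm = baseline * np.where(s.iron == "deficient", 2.0 ** delta, 1.0)
        mu = fpkm * lengths * cfg.depth / 1e9
        cols[s.sample_id] = _nb_draw(rng, mu, cfg.nb_dispersion)
    values = pd.DataFrame(cols, index=pd.Index(ids, name="transcript_id"))
    return ExpressionMatrix(values.astype(float), samples, "count"), samples


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Annotation plus counts: the full synthetic study."""
    study = simulate_annotation(cfg)
    study.counts, study.samples = simulate_counts(cfg, study.transcripts, study.truth)
    return study


def simulate_matrix_study(
    n_transcripts: int,
    de_per_class: Mapping[str, int],
    seed: int,
    planted_log2fc: float = 3.0,
    planted_baseline_fpkm: float = 40.0,
    planted_down_baseline_fpkm: float = 500.0,
    nb_dispersion: float = 0.05,
    n_replicates: int = 3,
    depth: float = 3e6,
    baseline_fpkm_log_mean: float = 3.0,
    baseline_fpkm_log_sigma: float = 1.5,
) -> tuple[ExpressionMatrix, list[TranscriptModel], pd.DataFrame]:
    """Expression-only study (no genome): background plus planted DE.

    Used for DE calibration runs — the null when ``de_per_class`` is empty.
    """
    rng = np.random.default_rng(seed)
    ids = [f"TX{i + 1:05d}" for i in range(n_transcripts)]
    lengths = rng.integers(300, 1500, n_transcripts)
    models = []
    pos = 0
    for tid, ln in zip(ids, lengths):
        iv = GenomicInterval("sim", pos, pos + int(ln), "+")
        models.append(TranscriptModel(tid, tid, iv, [iv]))
        pos += int(ln) + 100
    de_ids = ids[: sum(de_per_class.values())]
    classes = _assign_de_classes(de_per_class, de_ids)
    rows = []
    for tid in ids:
        cls = classes.get(tid, "none")
        s, r = _CLASS_STATUS[cls]
        rows.append({"transcript_id": tid, "de_class": cls,
                     "de_shoot": s, "de_root": r})
    truth = pd.DataFrame(rows).set_index("transcript_id")
    cfg = SimConfig(
        seed=seed,
        planted_log2fc=planted_log2fc,
        planted_baseline_fpkm=planted_baseline_fpkm,
        planted_down_baseline_fpkm=planted_down_baseline_fpkm,
        nb_dispersion=nb_dispersion,
        n_replicates=n_replicates,
        depth=depth,
        baseline_fpkm_log_mean=baseline_fpkm_log_mean,
        baseline_fpkm_log_sigma=baseline_fpkm_log_sigma,
    )
    counts, _samples = simulate_counts(cfg, models, truth)
    return counts, models, truth


# ---------------------------------------------------------------------------
# writers

def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Emit the exact input formats the pipeline consumes, plus the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(study.transcripts, outdir / "transcripts.gtf")
    write_fasta(study.genome, outdir / "genome.fa")
    write_mirna_tsv(study.mirnas, outdir / "mirna.tsv")
    study.truth.sort_index().to_csv(outdir / "truth.tsv", sep="\t")
    with open(outdir / "go_annotation.tsv", "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for g in sorted(study.go_annotation):
            for term in sorted(study.go_annotation[g]):
                fh.write(f"{g}\t{term}\n")
    with open(outdir / "go_terms.tsv", "w") as fh:
        fh.write("term_id\tname\tnamespace\n")
        for term in sorted(study.go_terms):
            name, ns = study.go_terms[term]
            fh.write(f"{term}\t{name}\t{ns}\n")
    with open(outdir / "fe_genes.txt", "w") as fh:
        for g in study.fe_genes:
            fh.write(g + "\n")
    with open(outdir / "mature_mirna.txt", "w") as fh:
        fh.write(f"simR1\t{study.mature_mirna}\n")
    if study.counts is not None:
        write_counts_tsv(study.counts, outdir / "counts.tsv")
        write_design_tsv(study.samples, outdir / "design.tsv")
    with open(outdir / "simconfig.json", "w") as fh:
        json.dump(asdict(study.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
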