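"""lncRNA-miRNA linkages: precursors, target prediction, target mimics.

Three relationships are detected. A lncRNA hosts a miRNA when the
pre-miRNA genomic locus lies entirely within the lncRNA's exons on the
same strand. A transcript is a miRNA target when a gapless antiparallel
alignment of the mature miRNA scores an expectation <= 2.0 under the
position-weighted penalty scheme (mismatch 1, G:U 0.5, doubled over miRNA
positions 2-13) with fewer than two mismatches and fewer than two G:U
pairs. A lncRNA is an endogenous target mimic (eTM) when it pairs the
miRNA with a perfect Watson-Crick seed (positions 2-8), a 3-nt bulge
inserted between the bases opposite positions 10 and 11 (blocking
cleavage), and at most three mismatches elsewhere.

Alignment diagrams use the conventional pairing notation: ``|`` for a
Watson-Crick pair, ``:`` for a G:U wobble (the two vertical dots of the
figure convention, rendered as a colon in one text column) and ``0`` for a
mismatch; bulged bases face ``-`` gap characters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .core_io import GenomicInterval, TranscriptModel

__all__ = [
    "PreMirnaLocus",
    "MirnaTargetHit",
    "EtmHit",
    "find_precursor_lncrnas",
    "predict_mirna_targets",
    "find_etm",
    "parse_alignment",
    "read_mirna_tsv",
    "write_mirna_tsv",
]

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}

DEFAULT_MAX_EXPECTATION = 2.0
SEED_WEIGHT_RANGE = range(2, 14)  # miRNA positions with doubled penalties
ETM_BULGE_LEN = 3
ETM_SEED = range(2, 9)  # positions requiring perfect Watson-Crick pairing
ETM_MAX_NONSEED_MISMATCH = 3


@dataclass(frozen=True)
class PreMirnaLocus:
    mirna_id: str
    locus: GenomicInterval
    mature_seq: str

    def __post_init__(self) -> None:
        if len(self.mature_seq) < 18:
            raise ValueError(f"{self.mirna_id}: mature sequence shorter than 18 nt")
        if self.locus.length() < len(self.mature_seq):
            raise ValueError(f"{self.mirna_id}: locus shorter than mature miRNA")


@dataclass(frozen=True)
class MirnaTargetHit:
    mirna_id: str
    target_id: str
    target_start: int  # 0-based position of the site on the target
    expectation: float
    n_mismatch: int
    n_gu: int
    inhibition: str  # cleavage | translation
    alignment: str


@dataclass(frozen=True)
class EtmHit:
    mirna_id: str
    lncrna_id: str
    site_start: int
    bulge_len: int
    bulge_position: tuple[int, int]  # miRNA 5'-position pair it interrupts
    n_mismatch: int
    n_gu: int
    alignment: str


def _pair_symbol(a: str, b: str) -> str:
    if (a, b) in _WC:
        return "|"
    if (a, b) in _GU:
        return ":"
    return "0"


def _check_mirna(mirna: str) -> None:
    if not (18 <= len(mirna) <= 26):
        raise ValueError(f"mature miRNA must be 18-26 nt, got {len(mirna)}")
    bad = set(mirna) - set("ACGU")
    if bad:
        raise ValueError(f"invalid miRNA character(s): {sorted(bad)}")


# ---------------------------------------------------------------------------
# precursors

def find_precursor_lncrnas(
    lncs: Iterable[TranscriptModel], pres: Iterable[PreMirnaLocus]
) -> list[tuple[str, str]]:
    """(lncrna_id, mirna_id) pairs where the pre-miRNA locus sits inside
    the lncRNA's exons on the same strand. Containment must be exonic: the
    locus length must be fully covered by exon overlap."""
    out: list[tuple[str, str]] = []
    for lnc in lncs:
        for pre in pres:
            loc = pre.locus
            if loc.chrom != lnc.chrom or loc.strand != lnc.strand:
                continue
            covered = sum(e.overlap(loc) for e in lnc.exons)
            if covered == loc.length():
                out.append((lnc.transcript_id, pre.mirna_id))
    return out


# ---------------------------------------------------------------------------
# target prediction

def _render_target_alignment(window: str, mirna: str, symbols: str) -> str:
    # columns follow the target 5'->3'; the miRNA is antiparallel (3'->5')
    return (
        f"target 5' {window} 3'\n"
        f"          {symbols}\n"
        f"miRNA  3' {mirna[::-1]} 5'"
    )


def predict_mirna_targets(
    mirna: str,
    targets: Mapping[str, str],
    mirna_id: str = "miRNA",
    e_max: float = DEFAULT_MAX_EXPECTATION,
    max_mismatch: int = 2,
    max_gu: int = 2,
) -> list[MirnaTargetHit]:
    """Slide the miRNA along each target and emit expectation-scored hits.

    Penalties per aligned miRNA position (1 = 5' end): Watson-Crick 0,
    G:U 0.5, mismatch 1.0, doubled for positions 2-13. A hit needs
    expectation <= e_max, n_mismatch < max_mismatch and n_gu < max_gu.
    Cleavage is called when positions 9-11 are all Watson-Crick paired.
    Overlapping hits on one target reduce to the minimum-expectation one
    (ties to the leftmost).
    """
    _check_mirna(mirna)
    L = len(mirna)
    hits: list[MirnaTargetHit] = []
    for target_id in targets:
        seq = targets[target_id]
        raw: list[MirnaTargetHit] = []
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            expectation = 0.0
            n_mismatch = n_gu = 0
            symbols = []
            central_wc = True
            for p in range(1, L + 1):
                tbase = window[L - p]  # miRNA 5' end faces the window 3' end
                sym = _pair_symbol(mirna[p - 1], tbase)
                symbols.append(sym)
                penalty = {"|": 0.0, ":": 0.5, "0": 1.0}[sym]
                if p in SEED_WEIGHT_RANGE:
                    penalty *= 2.0
                expectation += penalty
                if sym == ":":
                    n_gu += 1
                elif sym == "0":
                    n_mismatch += 1
                if p in (9, 10, 11) and sym != "|":
                    central_wc = False
            if expectation > e_max or n_mismatch >= max_mismatch or n_gu >= max_gu:
                continue
            # symbols were appended miRNA-5'-first = target-3'-first; flip so
            # the diagram columns run with the target 5'->3'
            sym_line = "".join(reversed(symbols))
            raw.append(
                MirnaTargetHit(
                    mirna_id,
                    target_id,
                    i,
                    expectation,
                    n_mismatch,
                    n_gu,
                    "cleavage" if central_wc else "translation",
                    _render_target_alignment(window, mirna, sym_line),
                )
            )
        # non-overlap reduction, best (lowest expectation, leftmost) first
        kept: list[MirnaTargetHit] = []
        for hit in sorted(raw, key=lambda h: (h.expectation, h.target_start)):
            if all(
                hit.target_start + L <= k.target_start
                or k.target_start + L <= hit.target_start
                for k in kept
            ):
                kept.append(hit)
        hits.extend(sorted(kept, key=lambda h: h.target_start))
    return hits


# ---------------------------------------------------------------------------
# endogenous target mimics

def find_etm(
    mirna: str,
    lnc_seqs: Mapping[str, str],
    mirna_id: str = "miRNA",
    max_nonseed_mismatch: int = ETM_MAX_NONSEED_MISMATCH,
) -> list[EtmHit]:
    """Detect endogenous target-mimic sites in lncRNA sequences.

    A window of miRNA length + 3 pairs the miRNA antiparallel with a 3-nt
    unpaired lncRNA bulge between the bases opposite miRNA positions 10 and
    11; positions 2-8 must be perfect Watson-Crick; outside the seed at
    most ``max_nonseed_mismatch`` mismatches are tolerated, with G:U
    counted as pairing.
    """
    _check_mirna(mirna)
    L = len(mirna)
    W = L + ETM_BULGE_LEN
    hits: list[EtmHit] = []
    for lnc_id in lnc_seqs:
        seq = lnc_seqs[lnc_id]
        raw: list[EtmHit] = []
        for i in range(len(seq) - W + 1):
            w = seq[i : i + W]
            n_mismatch = n_gu = 0
            ok = True
            cols: list[str] = []  # match-line columns, window 5'->3'
            mline: list[str] = []  # miRNA base per column (3'->5')
            for c in range(W):
                if L - 10 <= c <= L - 8:  # the 3-nt bulge
                    cols.append(" ")
                    mline.append("-")
                    continue
                p = W - c if c >= L - 7 else L - c
                sym = _pair_symbol(mirna[p - 1], w[c])
                cols.append(sym)
                mline.append(mirna[p - 1])
                if p in ETM_SEED:
                    if sym != "|":
                        ok = False
                        break
                else:
                    if sym == "0":
                        n_mismatch += 1
                    elif sym == ":":
                        n_gu += 1
            if not ok or n_mismatch > max_nonseed_mismatch:
                continue
            alignment = (
                f"lncRNA 5' {w} 3'\n"
                f"          {''.join(cols)}\n"
                f"miRNA  3' {''.join(mline)} 5'"
            )
            raw.append(
                EtmHit(
                    mirna_id, lnc_id, i, ETM_BULGE_LEN, (10, 11),
                    n_mismatch, n_gu, alignment,
                )
            )
        kept: list[EtmHit] = []
        for hit in sorted(raw, key=lambda h: (h.n_mismatch, h.n_gu, h.site_start)):
            if all(
                hit.site_start + W <= k.site_start
                or k.site_start + W <= hit.site_start
                for k in kept
            ):
                kept.append(hit)
        hits.extend(sorted(kept, key=lambda h: h.site_start))
    return hits


def parse_alignment(diagram: str) -> dict:
    """Recover (n_mismatch, n_gu, bulge columns) from an emitted diagram."""
    lines = diagram.split("\n")
    if len(lines) != 3:
        raise ValueError("expected a 3-line alignment diagram")
    match_line = lines[1][10:]
    bottom = lines[2][10:].split(" ")[0]
    bulge_cols = [c for c, ch in enumerate(bottom) if ch == "-"]
    return {
        "n_mismatch": match_line.count("0"),
        "n_gu": match_line.count(":"),
        "bulge_cols": bulge_cols,
    }


# ---------------------------------------------------------------------------
# I/O

def read_mirna_tsv(path) -> list[PreMirnaLocus]:
    """TSV columns: mirna_id, chrom, start, end, strand, mature_seq
    (coordinates 0-based half-open, matching the package convention)."""
    out: list[PreMirnaLocus] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 2:
                continue
            out.append(
                PreMirnaLocus(
                    f[idx["mirna_id"]],
                    GenomicInterval(
                        f[idx["chrom"]],
                        int(f[idx["start"]]),
                        int(f[idx["end"]]),
                        f[idx["strand"]],
                    ),
                    f[idx["mature_seq"]],
                )
            )
    return out


def write_mirna_tsv(pres: Iterable[PreMirnaLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tchrom\tstart\tend\tstrand\tmature_seq\n")
        for p in pres:
            fh.write(
                f"{p.mirna_id}\t{p.locus.chrom}\t{p.locus.start}\t{p.locus.end}\t"
                f"{p.locus.strand}\t{p.mature_seq}\n"
            )
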