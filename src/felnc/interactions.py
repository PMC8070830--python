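"""Cis/trans lncRNA-mRNA target prediction, GO enrichment, networks.

The interaction engine hybridizes two RNAs as a gapless antiparallel
duplex: over every register of one sequence against the reverse of the
other, consecutive complementary positions (Watson-Crick or G:U) form
stacks whose nearest-neighbor energies are summed; the duplex free energy
dG is the minimum run sum over all registers, and ndG normalizes dG by the
shorter sequence length. Cis targets are coding genes within 10 kb of a
differentially expressed lncRNA with ndG < -0.2; trans targets are
DE-mRNAs pairing any DE-lncRNA with ndG < -0.1. Trans-target gene sets are
tested for biological-process GO enrichment with an upper-tail
hypergeometric probability (p < 0.001, no multiplicity correction), and
lncRNA-mRNA networks restricted to curated Fe-related genes are exported
in Cytoscape-compatible SIF + attribute-table form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .core_io import TranscriptModel
from .energy_params import PAIR_CODE, STACK_ENERGY, encode

__all__ = [
    "DuplexEnergy",
    "TargetEdge",
    "GOResult",
    "pairing_free_energy",
    "find_cis_targets",
    "find_trans_targets",
    "go_enrichment",
    "build_network",
    "CIS_WINDOW_NT",
    "CIS_NDG_MAX",
    "TRANS_NDG_MAX",
    "GO_P_MAX",
    "HUB_MIN_DEGREE",
]

CIS_WINDOW_NT = 10_000
CIS_NDG_MAX = -0.2
TRANS_NDG_MAX = -0.1
GO_P_MAX = 0.001
HUB_MIN_DEGREE = 5  # hubs interact with MORE than this many Fe genes

MIN_DUPLEX_SEQ_LEN = 10


@dataclass(frozen=True)
class DuplexEnergy:
    dG: float  # kcal/mol, <= 0
    paired_len: int  # nt in the minimum-energy stacked run
    ndG: float  # kcal/mol per nt of the shorter sequence


@dataclass(frozen=True)
class TargetEdge:
    lncrna_id: str
    gene_id: str
    mode: str  # cis | trans
    distance: int | None  # nt span gap, cis only
    ndG: float


@dataclass(frozen=True)
class GOResult:
    term_id: str
    term_name: str
    namespace: str
    k: int  # selected genes carrying the term
    K: int  # universe genes carrying the term
    n: int  # selected set size
    N: int  # universe size
    p: float


def pairing_free_energy(a: str, b: str) -> DuplexEnergy:
    """Minimum-free-energy gapless complementary duplex of two RNAs.

    Dynamic program over all registers of ``a`` against the reverse of
    ``b``; consecutive paired steps contribute nearest-neighbor stack
    energies, a non-pairing position ends the run. ndG = dG / min length.
    A duplex needs at least two consecutive pairs; otherwise dG = ndG = 0.
    """
    if len(a) < MIN_DUPLEX_SEQ_LEN or len(b) < MIN_DUPLEX_SEQ_LEN:
        raise ValueError(
            f"sequences must be >= {MIN_DUPLEX_SEQ_LEN} nt for duplex prediction"
        )
    ca = encode(a.replace("T", "U").upper())
    cb = encode(b.replace("T", "U").upper()[::-1])
    # pair codes of every a_i vs reversed-b_j cell
    pc = PAIR_CODE[ca[:, None], cb[None, :]]
    # energy of the step from cell (i, j) to (i+1, j+1); 0 if either unpaired
    step = STACK_ENERGY[pc[:-1, :-1], pc[1:, 1:]]
    la, lb = len(ca), len(cb)
    run = np.zeros(lb)  # run sum ending at cell (i, j), current row i
    length = np.zeros(lb, dtype=np.intp)  # stacked pairs in that run
    best = 0.0
    best_pairs = 0
    for i in range(la - 1):
        valid = step[i] != 0.0
        nrun = np.zeros(lb)
        nlen = np.zeros(lb, dtype=np.intp)
        nrun[1:] = np.where(valid, run[:-1] + step[i], 0.0)
        nlen[1:] = np.where(valid, length[:-1] + 1, 0)
        j = int(np.argmin(nrun))
        if nrun[j] < best:
            best = float(nrun[j])
            best_pairs = int(nlen[j]) + 1
        run, length = nrun, nlen
    ndg = best / min(la, lb)
    return DuplexEnergy(best, best_pairs, ndg)


def find_cis_targets(
    lncs: Sequence[TranscriptModel],
    lnc_seqs: Mapping[str, str],
    genes: Sequence[TranscriptModel],
    gene_seqs: Mapping[str, str],
    de_lnc_ids: Iterable[str],
    window: int = CIS_WINDOW_NT,
    ndg_max: float = CIS_NDG_MAX,
) -> list[TargetEdge]:
    """Coding genes within ``window`` nt of a DE-lncRNA and ndG < ndg_max.

    Distance is the span gap on either side, irrespective of the gene's
    strand; overlapping spans give distance 0.
    """
    de = set(de_lnc_ids)
    edges: list[TargetEdge] = []
    for lnc in lncs:
        if lnc.transcript_id not in de:
            continue
        for gene in genes:
            if gene.chrom != lnc.chrom:
                continue
            gap = lnc.span.gap(gene.span)
            if gap > window:
                continue
            e = pairing_free_energy(
                lnc_seqs[lnc.transcript_id], gene_seqs[gene.transcript_id]
            )
            if e.ndG < ndg_max:
                edges.append(
                    TargetEdge(lnc.transcript_id, gene.gene_id, "cis", gap, e.ndG)
                )
    return edges


def find_trans_targets(
    lnc_seqs: Mapping[str, str],
    mrna_seqs: Mapping[str, str],
    ndg_max: float = TRANS_NDG_MAX,
) -> list[TargetEdge]:
    """All-vs-all duplex scan of DE-lncRNAs against DE-mRNAs.

    Both maps must already be restricted to differentially expressed
    transcripts; pairs with ndG < ndg_max become trans edges. A pair
    already linked in cis stays eligible — the two modes are independent.
    """
    edges: list[TargetEdge] = []
    for lnc_id in lnc_seqs:
        for mrna_id in mrna_seqs:
            e = pairing_free_energy(lnc_seqs[lnc_id], mrna_seqs[mrna_id])
            if e.ndG < ndg_max:
                edges.append(TargetEdge(lnc_id, mrna_id, "trans", None, e.ndG))
    return edges


def go_enrichment(
    selected: Iterable[str],
    universe: Iterable[str],
    annot: Mapping[str, Iterable[str]],
    terms: Mapping[str, tuple[str, str]],
    p_max: float = GO_P_MAX,
) -> list[GOResult]:
    """Upper-tail hypergeometric enrichment of biological-process terms.

    ``annot`` maps gene -> term ids; ``terms`` maps term id -> (name,
    namespace). Unannotated universe genes still count in N. Results with
    p < p_max are returned sorted by (p, term_id).
    """
    sel = set(selected)
    uni = set(universe)
    if not sel <= uni:
        raise ValueError("selected gene set is not a subset of the universe")
    N, n = len(uni), len(sel)
    term_universe: dict[str, set[str]] = {}
    for gene in uni:
        for term in annot.get(gene, ()):  # noqa: B905
            term_universe.setdefault(term, set()).add(gene)
    results: list[GOResult] = []
    for term_id, genes_with in term_universe.items():
        name, namespace = terms.get(term_id, (term_id, "biological_process"))
        if namespace != "biological_process":
            continue
        K = len(genes_with)
        k = len(genes_with & sel)
        p = float(hypergeom.sf(k - 1, N, K, n))
        if p < p_max:
            results.append(
                GOResult(term_id, name, namespace, k, K, n, N, p)
            )
    return sorted(results, key=lambda r: (r.p, r.term_id))


def build_network(
    edges: Sequence[TargetEdge],
    de_direction: Mapping[str, str],
    fe_genes: Iterable[str],
    outdir: str | Path | None = None,
) -> nx.Graph:
    """Fe-gene interaction network from trans edges.

    Keeps only trans edges whose gene is in the curated Fe-related list.
    Node attributes: ``type`` (lncRNA/mRNA) and ``direction`` (the DE call
    passed in ``de_direction``). lncRNAs of degree > 5 are flagged as hubs.
    When ``outdir`` is given, writes ``network.sif`` plus node/edge
    attribute TSVs loadable by standard network viewers.
    """
    fe = set(fe_genes)
    g = nx.Graph()
    for e in edges:
        if e.mode != "trans" or e.gene_id not in fe:
            continue
        g.add_node(e.lncrna_id, type="lncRNA",
                   direction=de_direction.get(e.lncrna_id, "ns"))
        g.add_node(e.gene_id, type="mRNA",
                   direction=de_direction.get(e.gene_id, "ns"))
        g.add_edge(e.lncrna_id, e.gene_id, ndG=e.ndG)
    for node, data in g.nodes(data=True):
        data["hub"] = data["type"] == "lncRNA" and g.degree(node) > HUB_MIN_DEGREE
    if outdir is not None:
        outdir = Path(outdir)
        with open(outdir / "network.sif", "w") as fh:
            for u, v in sorted(g.edges()):
                lnc, gene = (u, v) if g.nodes[u]["type"] == "lncRNA" else (v, u)
                fh.write(f"{lnc}\ttrans\t{gene}\n")
        with open(outdir / "network_nodes.tsv", "w") as fh:
            fh.write("node\ttype\tdirection\thub\n")
            for node in sorted(g.nodes()):
                d = g.nodes[node]
                fh.write(f"{node}\t{d['type']}\t{d['direction']}\t{d['hub']}\n")
        with open(outdir / "network_edges.tsv", "w") as fh:
            fh.write("lncrna_id\tgene_id\tndG\n")
            for u, v in sorted(g.edges()):
                lnc, gene = (u, v) if g.nodes[u]["type"] == "lncRNA" else (v, u)
                fh.write(f"{lnc}\t{gene}\t{g.edges[u, v]['ndG']:.6g}\n")
    return g
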