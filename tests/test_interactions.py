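"""Duplex free energy, target thresholds, GO enrichment, networks."""

import math
from itertools import combinations

import numpy as np
import pytest

from felnc.core_io import GenomicInterval, TranscriptModel
from felnc.energy_params import PAIR_CODE, STACK_ENERGY, encode
from felnc.interactions import (
    TargetEdge,
    build_network,
    find_cis_targets,
    find_trans_targets,
    go_enrichment,
    pairing_free_energy,
)

RC = str.maketrans("ACGU", "UGCA")


def _rc(seq):
    return seq.translate(RC)[::-1]


def _brute_force_dg(a, b):
    """Exhaustive enumeration over every register and window."""
    ca, cb = encode(a), encode(b[::-1])
    best = 0.0
    la, lb = len(ca), len(cb)
    for off in range(-(lb - 1), la):
        # cells (i, j) on this diagonal: j = i - off
        cells = [
            (i, i - off) for i in range(max(0, off), min(la, lb + off))
        ]
        for s in range(len(cells)):
            total = 0.0
            for t in range(s + 1, len(cells)):
                i1, j1 = cells[t - 1]
                i2, j2 = cells[t]
                e = STACK_ENERGY[PAIR_CODE[ca[i1], cb[j1]], PAIR_CODE[ca[i2], cb[j2]]]
                if e == 0.0:
                    break
                total += e
                best = min(best, total)
    return best


class TestDuplexEnergy:
    def test_matches_exhaustive_enumeration_on_short_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            la, lb = rng.integers(10, 16, 2)
            a = "".join(rng.choice(list("ACGU"), la))
            b = "".join(rng.choice(list("ACGU"), lb))
            assert pairing_free_energy(a, b).dG == pytest.approx(_brute_force_dg(a, b))

    def test_perfect_complement_beats_mismatched_variant(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGU"), 25))
        perfect = pairing_free_energy(a, _rc(a))
        assert perfect.dG < 0 and perfect.paired_len == 25
        broken = list(_rc(a))
        for i in (10, 12, 14):
            broken[i] = {"A": "C", "C": "A", "G": "A", "U": "C"}[broken[i]]
        mismatched = pairing_free_energy(a, "".join(broken))
        assert perfect.ndG < mismatched.ndG

    def test_no_complementarity_gives_zero(self):
        e = pairing_free_energy("A" * 25, "A" * 25)
        assert e.dG == 0.0 and e.ndG == 0.0 and e.paired_len == 0

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGU"), 30))
            b = "".join(rng.choice(list("ACGU"), 45))
            assert pairing_free_energy(a, b).dG == pytest.approx(
                pairing_free_energy(b, a).dG
            )

    def test_ndg_normalizes_by_shorter_sequence(self):
        a = "GCGCGCGCGCGC"
        e = pairing_free_energy(a, _rc(a) + "A" * 30)
        assert e.ndG == pytest.approx(e.dG / 12)

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            pairing_free_energy("ACGUA", "ACGUACGUAC")

    def test_dna_input_accepted_as_rna(self):
        assert pairing_free_energy("GCGCGCGCGCT", "AGCGCGCGCGC").dG < 0


def _tm(tid, start, end, strand="+", gene=None, chrom="c", biotype="coding"):
    iv = GenomicInterval(chrom, start, end, strand)
    return TranscriptModel(tid, gene or tid, iv, [iv], biotype)


def _strong_pair(rng, lnc_len=400, cassette=60):
    """lncRNA and mRNA sharing a reverse-complement cassette."""
    c = "".join(rng.choice(list("GC"), cassette))
    lnc = (
        "".join(rng.choice(list("ACU"), 100))
        + _rc(c)
        + "".join(rng.choice(list("ACU"), lnc_len - 100 - cassette))
    )
    mrna = "".join(rng.choice(list("ACU"), 200)) + c + "".join(
        rng.choice(list("ACU"), 400)
    )
    return lnc, mrna


class TestTargetThresholds:
    def setup_method(self):
        rng = np.random.default_rng(21)
        self.lnc_seq, self.mrna_seq = _strong_pair(rng)
        # a moderately pairing variant landing between -0.2 and -0.1
        self.ndg = pairing_free_energy(self.lnc_seq, self.mrna_seq).ndG
        assert self.ndg < -0.2

    def _mid_pair(self):
        rng = np.random.default_rng(22)
        lnc, mrna = _strong_pair(rng, cassette=22)
        ndg = pairing_free_energy(lnc, mrna).ndG
        assert -0.2 < ndg < -0.1
        return lnc, mrna, ndg

    def test_gene_outside_10kb_window_never_cis(self):
        lnc = _tm("l", 0, 400, biotype="lncRNA")
        gene = _tm("tg", 12_400, 13_000, gene="g")
        edges = find_cis_targets(
            [lnc], {"l": self.lnc_seq}, [gene], {"tg": self.mrna_seq}, ["l"]
        )
        assert edges == []

    def test_mid_strength_pair_fails_cis_but_passes_trans(self):
        lnc_seq, mrna_seq, ndg = self._mid_pair()
        lnc = _tm("l", 0, 400, biotype="lncRNA")
        gene = _tm("tg", 4400, 5000, gene="g")
        cis = find_cis_targets([lnc], {"l": lnc_seq}, [gene], {"tg": mrna_seq}, ["l"])
        assert cis == []
        trans = find_trans_targets({"l": lnc_seq}, {"tg": mrna_seq})
        assert len(trans) == 1 and trans[0].ndG == pytest.approx(ndg)

    def test_strong_pair_in_window_is_cis(self):
        lnc = _tm("l", 0, 400, biotype="lncRNA")
        gene = _tm("tg", 8400, 9000, gene="g")
        (edge,) = find_cis_targets(
            [lnc], {"l": self.lnc_seq}, [gene], {"tg": self.mrna_seq}, ["l"]
        )
        assert edge.mode == "cis" and edge.distance == 8000

    def test_non_de_lncrna_is_skipped(self):
        lnc = _tm("l", 0, 400, biotype="lncRNA")
        gene = _tm("tg", 4400, 5000, gene="g")
        assert (
            find_cis_targets([lnc], {"l": self.lnc_seq}, [gene],
                             {"tg": self.mrna_seq}, [])
            == []
        )

    def test_empty_de_mrna_set_gives_no_trans_edges(self):
        assert find_trans_targets({"l": self.lnc_seq}, {}) == []

    def test_lowering_threshold_never_adds_edges(self):
        rng = np.random.default_rng(30)
        lncs = {f"l{i}": "".join(rng.choice(list("ACGU"), 300)) for i in range(5)}
        mrnas = {f"m{i}": "".join(rng.choice(list("ACGU"), 300)) for i in range(5)}
        prev = None
        for ndg_max in (-0.02, -0.05, -0.1, -0.2):
            n = len(find_trans_targets(lncs, mrnas, ndg_max=ndg_max))
            if prev is not None:
                assert n <= prev
            prev = n

    def test_random_kb_pairs_rarely_link_in_trans(self):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGU"))
        n_edges = 0
        for _ in range(100):
            a = "".join(rng.choice(bases, 1000, p=[0.2, 0.3, 0.3, 0.2]))
            b = "".join(rng.choice(bases, 1000, p=[0.2, 0.3, 0.3, 0.2]))
            n_edges += len(find_trans_targets({"l": a}, {"m": b}))
        assert n_edges < 10

    def test_emitted_edges_satisfy_their_thresholds(self, study):
        from felnc.core_io import extract_transcript_sequence

        seqs = {
            t.transcript_id: extract_transcript_sequence(t, study.genome)
            for t in study.transcripts
        }
        truth = study.truth
        lncs = [t for t in study.transcripts
                if truth.loc[t.transcript_id, "kind"] == "lncRNA"]
        genes = [t for t in study.transcripts
                 if truth.loc[t.transcript_id, "kind"] == "coding"]
        de_lnc = [
            tid for tid in truth.index
            if truth.loc[tid, "kind"] == "lncRNA"
            and truth.loc[tid, "de_class"] != "none"
        ]
        for e in find_cis_targets(lncs, seqs, genes, seqs, de_lnc):
            assert e.distance <= 10_000 and e.ndG < -0.2
        de_mrna = [
            tid for tid in truth.index
            if truth.loc[tid, "kind"] == "coding"
            and truth.loc[tid, "de_class"] != "none"
        ]
        for e in find_trans_targets(
            {i: seqs[i] for i in de_lnc}, {i: seqs[i] for i in de_mrna}
        ):
            assert e.ndG < -0.1


def _exhaustive_p(N, K, n, k):
    """P(X >= k) by enumerating every n-subset of an N-universe."""
    universe = range(N)
    marked = set(range(K))
    hits = total = 0
    for subset in combinations(universe, n):
        total += 1
        if len(marked.intersection(subset)) >= k:
            hits += 1
    return hits / total


class TestGoEnrichment:
    def test_matches_exhaustive_enumeration(self):
        annot = {f"g{i}": ["T1"] if i < 5 else [] for i in range(20)}
        terms = {"T1": ("term one", "biological_process")}
        universe = list(annot)
        for selected in (["g0", "g1", "g2", "g3", "g4"],
                         ["g0", "g1", "g7", "g8", "g9"]):
            res = go_enrichment(selected, universe, annot, terms, p_max=1.1)
            k = sum(1 for g in selected if "T1" in annot[g])
            want = _exhaustive_p(20, 5, 5, k)
            assert res[0].p == pytest.approx(want, abs=1e-12)

    def test_fully_selected_term_value(self):
        annot = {f"g{i}": ["T1"] if i < 5 else [] for i in range(20)}
        terms = {"T1": ("term one", "biological_process")}
        res = go_enrichment([f"g{i}" for i in range(5)], list(annot), annot, terms)
        assert res[0].p == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_term_annotating_everything_is_never_enriched(self):
        annot = {f"g{i}": ["T1"] for i in range(10)}
        terms = {"T1": ("everything", "biological_process")}
        res = go_enrichment(["g0", "g1"], list(annot), annot, terms, p_max=1.1)
        assert res[0].p == pytest.approx(1.0)
        assert go_enrichment(["g0", "g1"], list(annot), annot, terms) == []

    def test_empty_selection_gives_empty_result(self):
        annot = {"g0": ["T1"], "g1": []}
        terms = {"T1": ("t", "biological_process")}
        assert go_enrichment([], list(annot), annot, terms) == []

    def test_non_bp_namespaces_are_skipped(self):
        annot = {"g0": ["T1"], "g1": [], "g2": [], "g3": []}
        terms = {"T1": ("binding", "molecular_function")}
        assert go_enrichment(["g0"], list(annot), annot, terms, p_max=1.1) == []

    def test_selection_outside_universe_raises(self):
        with pytest.raises(ValueError, match="subset"):
            go_enrichment(["x"], ["g0"], {}, {})


class TestNetwork:
    def test_single_edge_network(self):
        edges = [TargetEdge("l1", "g1", "trans", None, -0.3)]
        g = build_network(edges, {"l1": "up", "g1": "down"}, ["g1"])
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        assert g.nodes["l1"]["type"] == "lncRNA"
        assert g.nodes["g1"]["direction"] == "down"

    def test_empty_fe_list_gives_empty_network(self):
        edges = [TargetEdge("l1", "g1", "trans", None, -0.3)]
        assert build_network(edges, {}, []).number_of_nodes() == 0

    def test_cis_edges_are_excluded(self):
        edges = [TargetEdge("l1", "g1", "cis", 100, -0.3)]
        assert build_network(edges, {}, ["g1"]).number_of_edges() == 0

    def test_degree_six_lncrna_is_flagged_as_hub(self):
        fe = [f"g{i}" for i in range(6)]
        edges = [TargetEdge("l1", g, "trans", None, -0.2) for g in fe]
        edges.append(TargetEdge("l2", "g0", "trans", None, -0.2))
        g = build_network(edges, {}, fe)
        assert g.nodes["l1"]["hub"] is True
        assert g.nodes["l2"]["hub"] is False

    def test_sif_export(self, tmp_path):
        edges = [TargetEdge("l1", "g1", "trans", None, -0.3)]
        build_network(edges, {"l1": "up"}, ["g1"], outdir=tmp_path)
        assert (tmp_path / "network.sif").read_text() == "l1\ttrans\tg1\n"
        nodes = (tmp_path / "network_nodes.tsv").read_text().splitlines()
        assert nodes[0] == "node\ttype\tdirection\thub"
        assert len(nodes) == 3
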