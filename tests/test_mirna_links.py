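"""Precursor containment, expectation-scored targets, and target mimics."""

import numpy as np
import pytest

from felnc.core_io import GenomicInterval, TranscriptModel
from felnc.mirna_links import (
    EtmHit,
    PreMirnaLocus,
    find_etm,
    find_precursor_lncrnas,
    parse_alignment,
    predict_mirna_targets,
)

MIRNA = "UGACGGAAGGGCACUACCUAC"  # 21 nt
RC = str.maketrans("ACGU", "UGCA")


def _rc(seq):
    return seq.translate(RC)[::-1]


def _lnc(tid, chrom, exons, strand):
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    span = GenomicInterval(chrom, ivs[0].start, ivs[-1].end, strand)
    return TranscriptModel(tid, tid, span, ivs, "lncRNA")


def _pre(mid, chrom, start, end, strand):
    return PreMirnaLocus(mid, GenomicInterval(chrom, start, end, strand), MIRNA)


class TestPrecursors:
    def test_strict_containment_matches(self):
        lnc = _lnc("l", "chr1", [(1000, 2000)], "+")
        assert find_precursor_lncrnas([lnc], [_pre("m", "chr1", 1200, 1320, "+")]) == [
            ("l", "m")
        ]

    def test_partial_overlap_is_not_containment(self):
        lnc = _lnc("l", "chr1", [(1000, 2000)], "+")
        assert find_precursor_lncrnas([lnc], [_pre("m", "chr1", 1950, 2070, "+")]) == []

    def test_opposite_strand_never_matches(self):
        lnc = _lnc("l", "chr1", [(1000, 2000)], "+")
        assert find_precursor_lncrnas([lnc], [_pre("m", "chr1", 1200, 1320, "-")]) == []

    def test_locus_spanning_an_intron_is_not_exonic(self):
        lnc = _lnc("l", "chr1", [(1000, 1500), (1800, 2300)], "+")
        assert find_precursor_lncrnas([lnc], [_pre("m", "chr1", 1400, 1900, "+")]) == []
        assert find_precursor_lncrnas([lnc], [_pre("m", "chr1", 1850, 1990, "+")]) == [
            ("l", "m")
        ]

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(2)
        lncs, pres = [], []
        for i in range(30):
            start = int(rng.integers(0, 50_000))
            strand = "+-"[int(rng.integers(2))]
            lncs.append(_lnc(f"l{i}", "c", [(start, start + 600)], strand))
        for i in range(30):
            start = int(rng.integers(0, 50_000))
            strand = "+-"[int(rng.integers(2))]
            pres.append(_pre(f"m{i}", "c", start, start + 120, strand))
        got = set(find_precursor_lncrnas(lncs, pres))
        want = {
            (l.transcript_id, p.mirna_id)
            for l in lncs
            for p in pres
            if l.strand == p.locus.strand
            and l.span.start <= p.locus.start
            and p.locus.end <= l.span.end
        }
        assert got == want


def _site_with(mirna, subs=()):
    """Perfect complement site, then substitutions at given miRNA positions.

    ``subs`` maps miRNA 5'-position -> replacement target base.
    """
    site = list(_rc(mirna))
    L = len(mirna)
    for pos, base in subs:
        site[L - pos] = base
    return "".join(site)


class TestTargetPrediction:
    def test_perfect_complement_scores_zero_and_cleavage(self):
        target = "AAAA" + _site_with(MIRNA) + "GGGG"
        (hit,) = predict_mirna_targets(MIRNA, {"t": target})
        assert hit.expectation == 0.0
        assert (hit.n_mismatch, hit.n_gu) == (0, 0)
        assert hit.inhibition == "cleavage"
        assert hit.target_start == 4

    def test_single_wobble_and_seed_mismatch_scores(self):
        # construct explicitly: G at miRNA position 15 -> target U is a wobble
        mirna = "UGACGGAAGGGCACGACCUAC"  # position 15 = G
        site = _site_with(mirna, [(15, "U")])
        (hit,) = predict_mirna_targets(mirna, {"t": site})
        assert hit.expectation == 0.5
        assert (hit.n_mismatch, hit.n_gu) == (0, 1)
        # seed mismatch at position 5 carries a doubled penalty
        site2 = _site_with(mirna, [(5, "G")])  # position 5 = G, G:G mismatch
        (hit2,) = predict_mirna_targets(mirna, {"t": site2})
        assert hit2.expectation == 2.0
        assert hit2.n_mismatch == 1

    def test_two_mismatches_rejected_regardless_of_expectation(self):
        # both mismatches at unweighted 3' positions: expectation 2.0 <= e_max
        site = _site_with(MIRNA, [(15, "C"), (17, "C")])
        assert MIRNA[14] == "U" and MIRNA[16] == "C"  # both give mismatches
        assert predict_mirna_targets(MIRNA, {"t": site}) == []

    def test_two_wobbles_rejected(self):
        mirna = "UGACGGAAGGGCACGACGUAC"  # positions 15 and 18 are G
        site = _site_with(mirna, [(15, "U"), (18, "U")])
        assert predict_mirna_targets(mirna, {"t": site}) == []

    def test_expectation_is_additive_over_penalties(self):
        mirna = "UGACGGAAGGGCACGACCUAC"
        e_wobble = predict_mirna_targets(
            mirna, {"t": _site_with(mirna, [(15, "U")])}
        )[0].expectation
        e_mm = predict_mirna_targets(
            mirna, {"t": _site_with(mirna, [(16, "C")])}, e_max=3.0
        )[0].expectation
        both = predict_mirna_targets(
            mirna, {"t": _site_with(mirna, [(15, "U"), (16, "C")])}, e_max=3.0
        )[0].expectation
        assert both == pytest.approx(e_wobble + e_mm)

    def test_central_mismatch_calls_translational_inhibition(self):
        mirna = "UGACGGAAGGGCACGACCUAC"  # position 10 = G
        site = _site_with(mirna, [(10, "G")])  # (G, G) central mismatch
        (hit,) = predict_mirna_targets(mirna, {"t": site}, e_max=3.0)
        assert hit.inhibition == "translation"

    def test_overlapping_hits_reduce_to_best(self):
        site = _site_with(MIRNA)
        target = site + site  # two non-overlapping perfect sites survive
        hits = predict_mirna_targets(MIRNA, {"t": target})
        assert [h.target_start for h in hits] == [0, 21]

    def test_mirna_length_bounds(self):
        with pytest.raises(ValueError, match="18-26"):
            predict_mirna_targets("ACGU", {"t": "ACGU" * 10})


def _etm_window(mirna, bulge="CUU"):
    return _rc(mirna[10:]) + bulge + _rc(mirna[:10])


class TestEtm:
    def test_planted_mimic_site_is_found(self):
        lnc = "ACCA" + _etm_window(MIRNA) + "CCAA"
        (hit,) = find_etm(MIRNA, {"l": lnc})
        assert hit.site_start == 4
        assert hit.n_mismatch == 0
        assert hit.bulge_len == 3 and hit.bulge_position == (10, 11)

    def test_bulge_free_perfect_complement_is_not_a_mimic(self):
        lnc = "ACCA" + _rc(MIRNA) + "CCAA"
        assert find_etm(MIRNA, {"l": lnc}) == []

    def test_four_nonseed_mismatches_rejected(self):
        window = list(_etm_window(MIRNA))
        # corrupt four bases pairing non-seed miRNA positions 12, 14, 16, 18
        for i in (2, 4, 6, 8):  # window cols pair positions 21-i (>= 13)
            window[i] = {"A": "C", "C": "A", "G": "A", "U": "C"}[window[i]]
        lnc = "AAAA" + "".join(window) + "AAAA"
        assert find_etm(MIRNA, {"l": lnc}) == []

    def test_three_nonseed_mismatches_still_accepted(self):
        window = list(_etm_window(MIRNA))
        for i in (2, 4, 6):
            window[i] = {"A": "C", "C": "A", "G": "A", "U": "C"}[window[i]]
        lnc = "AAAA" + "".join(window) + "AAAA"
        (hit,) = find_etm(MIRNA, {"l": lnc})
        assert hit.n_mismatch == 3

    def test_seed_mismatch_rejected(self):
        window = list(_etm_window(MIRNA))
        col = len(window) - 5  # pairs miRNA position 5 (seed)
        window[col] = {"A": "C", "C": "A", "G": "A", "U": "C"}[window[col]]
        lnc = "AAAA" + "".join(window) + "AAAA"
        assert find_etm(MIRNA, {"l": lnc}) == []

    def test_shuffled_lncrnas_rarely_contain_mimics(self):
        """Dinucleotide-preserving shuffles should almost never produce a
        seed-perfect bulged site for a random miRNA."""
        rng = np.random.default_rng(9)
        mirna = "".join(rng.choice(list("ACGU"), 21))
        base = ["".join(rng.choice(list("ACGU"), 450)) for _ in range(4)]
        zero = 0
        for _ in range(100):
            shuffled = {}
            for i, seq in enumerate(base):
                pairs = [seq[j : j + 2] for j in range(0, len(seq), 2)]
                rng.shuffle(pairs)
                shuffled[f"l{i}"] = "".join(pairs)
            if not find_etm(mirna, shuffled):
                zero += 1
        assert zero >= 95


class TestDiagrams:
    def test_target_diagram_round_trip(self):
        mirna = "UGACGGAAGGGCACGACCUAC"
        site = _site_with(mirna, [(15, "U"), (16, "C")])
        (hit,) = predict_mirna_targets(mirna, {"t": site}, e_max=3.0)
        parsed = parse_alignment(hit.alignment)
        assert parsed["n_mismatch"] == hit.n_mismatch == 1
        assert parsed["n_gu"] == hit.n_gu == 1
        assert parsed["bulge_cols"] == []

    def test_etm_diagram_round_trip(self):
        lnc = "ACCA" + _etm_window(MIRNA) + "CCAA"
        (hit,) = find_etm(MIRNA, {"l": lnc})
        parsed = parse_alignment(hit.alignment)
        assert parsed["n_mismatch"] == hit.n_mismatch
        assert parsed["n_gu"] == hit.n_gu
        assert len(parsed["bulge_cols"]) == 3

    def test_planted_study_mimics_and_precursors_recovered(self, study):
        truth = study.truth
        lnc_models = [
            t for t in study.transcripts
            if truth.loc[t.transcript_id, "kind"] == "lncRNA"
        ]
        pairs = find_precursor_lncrnas(lnc_models, study.mirnas)
        want = {
            (tid, truth.loc[tid, "precursor_mirna"])
            for tid in truth.index[truth["precursor_mirna"] != ""]
        }
        assert set(pairs) == want
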