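# Methods

This note documents the models behind `felnc`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Coordinates and sequences

Internal coordinates are 0-based half-open on every type
(`GenomicInterval`, exons, pre-miRNA loci); on-disk GTF is 1-based
inclusive, converted at the boundary. This removes off-by-one ambiguity
from all overlap/distance code: `gap` of two intervals is
`max(0, max(starts) − min(ends))` and is 0 exactly when they touch or
overlap. Sequences are handled RNA-sense (U) internally; FASTA input may
use T. Minus-strand transcript sequences are reverse complements of the
genomic slice, exons spliced 5′→3′ in transcript orientation.

## Coding-potential score

The classifier role usually played by a database-backed coding-potential
tool is filled by a deterministic linear score over longest-ORF features,
because the pipeline must run self-contained with no protein database.
An ORF starts at an AUG in any forward frame; with an in-frame stop the
stop codon is included (integrity 1), an AUG running off the 3′ end
counts complete codons (integrity ½), no AUG gives length 0 (integrity
0). The weights (2 on log₁₀ ORF length centered at 300 nt, 3 on coverage
centered at 0.35, 0.5 on integrity) were fixed so that ORF-less and
short-ORF transcripts score clearly negative (an ORF-less transcript
scores ≈ −6.5) and canonical full-length ORFs score clearly positive
(≥ +1.5), preserving the standard sign convention: negative = noncoding.
A score of exactly 0 is assigned to the mRNA side so the lncRNA call
stays conservative (lncRNAs require strictly negative scores). The score
is strictly increasing in ORF length and coverage.

## Positional classification

Priority order: same-strand exonic overlap → cis-sense (overlap
evidence); opposite-strand exonic overlap → antisense; nearest
same-strand coding span with gap ≤ 500 nt → cis-sense (proximal
evidence); else intergenic. Overlap is computed exon-to-exon, not
span-to-span, so a lncRNA inside an intron does not count as overlapping
— it is caught by the proximal rule (span gap 0). Both upstream and
downstream neighbors qualify for the proximal rule, and the 500 nt bound
is inclusive. Sense-overlap and sense-proximal cases are one `cis_sense`
label with the evidence subtype recorded, since they form a single
category in the three-way classification this reproduces. Partners
maximize overlap (overlap cases) or minimize distance (proximal case);
ties break lexicographically on (gene_id, transcript_id) for
determinism. An interval tree indexes coding exons; a brute-force
all-pairs scan serves as the test oracle.

## Differential expression

The DE statistic is a replicate-based noise-dominance probability.
Decisions fixed here (the method family leaves them open):

- pseudocount k = 0.5 applied inside M only, never D;
- noise built from all unordered within-condition replicate pairs,
  pooled over both conditions and all transcripts (with 3 replicates per
  condition this gives 6 noise points per transcript);
- strict inequalities in the dominance count, so a transcript with
  M = D = 0 has probability exactly 0.

The filter (|M| > 1, FPKM > 2, probability > 0.8, all strict) uses
`fpkm_max = max(μ₊Fe, μ₋Fe)`, so a transcript silenced in one condition
remains callable. FPKM uses the column sum of the provided count matrix
as library size and transcript exonic length — self-contained choices, as
the upstream normalization denominator is not part of this artifact's
inputs. Transcripts with all-zero abundance in a tissue are reported as
`not_detected` rather than `ns`.

Expression classes map (shoot, root) status pairs: (ns, down) → I,
(ns, up) → II, (down, ns) → III, (up, ns) → IV, (up, up) → V. The three
remaining significant combinations (down/down, up/down, down/up) have no
class in this scheme and are emitted as `other` without guessing intent;
(ns, ns) is not emitted. No multiple-testing correction is applied — the
filter operates on the dominance probability, not on p-values.

## miRNA linkages

Precursor containment requires the pre-miRNA locus to lie entirely
within the lncRNA's exons on the same strand: a transcript can only be
the precursor of RNA encoded on its own strand within its own sequence.
No hairpin-structure validation is attempted (no folding engine);
containment is the criterion.

Target prediction uses the position-weighted expectation scheme
(mismatch 1.0, G:U 0.5, doubled over miRNA positions 2–13, 5′
numbering), emitting hits with expectation ≤ 2.0. "Fewer than two
mismatches and G:U pairs" is enforced as two independent caps
(n_mismatch < 2 AND n_gu < 2) — the stricter, reproducible reading; both
caps are arguments. Cleavage vs translational inhibition is decided by
Watson-Crick pairing at central positions 9–11 (a fixed choice between
the two conventions in use). Indels are not allowed in target
alignments, which keeps the scorer exhaustively checkable.

eTM detection requires a perfect Watson-Crick seed at positions 2–8, a
3-nt unpaired bulge in the lncRNA between the bases opposite positions
10 and 11 (the geometry that blocks cleavage), and at most 3 mismatches
outside the seed with G:U counted as pairing — the canonical
target-mimicry site architecture. Overlapping hits reduce to the best
(fewest mismatches, then leftmost). Alignment diagrams use `|` for
Watson-Crick pairs, `:` for G:U wobbles (one text column standing for
the two stacked dots of the figure convention) and `0` for mismatches;
bulged bases face `-`.

## Duplex free energy

Trans/cis interaction strength is the minimum-free-energy **gapless**
complementary duplex between one RNA and the reverse of the other: over
every register, consecutive paired positions (Watson-Crick or G:U) form
stacks whose nearest-neighbor energies are summed; a non-pairing
position terminates the run. The ten Watson-Crick stacking constants
are standard nearest-neighbor values (kcal/mol, 37 °C); wobble-containing
steps use two package constants (−1.20 with one G:U in the step, −0.50
with two), documented in `energy_params.py`. The −0.1 (trans) and −0.2
(cis) thresholds shipped as defaults are defined relative to this fixed
table. `ndG` normalizes dG by the **shorter** sequence, so a short
lncRNA pairing a long mRNA is judged by the lncRNA's length. The dynamic
program is an O(n·m) diagonal recurrence; exhaustive register/window
enumeration is the test oracle. Intramolecular structure and partition
functions are out of scope — this is hybridization energy only, as in
the tool class it replaces.

Cis search uses span-gap distance within 10 kb on either side,
irrespective of the gene's strand (upstream regulators and antisense
neighbors both qualify). Cis and trans modes are independent: a pair can
carry both edges.

## GO enrichment and networks

Enrichment is the upper-tail hypergeometric probability
P(X ≥ k | N, K, n) per biological-process term, with raw p-values
filtered at p < 0.001 (no multiplicity correction — the threshold is the
rule, deliberately). Annotation is flat: no propagation to ancestor
terms through the GO graph, noted as a limitation. Unannotated universe
genes count in N. Networks keep only trans edges into the curated
Fe-related gene list; lncRNAs with degree > 5 are flagged as hubs; SIF
plus node/edge attribute TSVs are written for standard viewers.

## Synthetic data

The generator emulates the study design end-to-end: a small
multi-chromosome genome; coding genes with 5′UTR + full ORF + CAT-free
3′UTR; lncRNAs generated AUG-free in every frame so their coding scores
are negative **by construction** (catalog recovery is exact, not
probabilistic); positional plants made geometrically unambiguous
(cis-sense at 100–500 nt same strand, antisense overlapping a gene's
3′UTR on the opposite strand, intergenic > 2 kb from everything);
pre-miRNA loci and eTM motifs planted inside differentially expressed
lncRNAs; 30-nt reverse-complement cassettes creating guaranteed trans
pairs and 60-nt cassettes for cis pairs at 8 kb. With lncRNA lengths of
400–480 nt, a 30-nt perfect cassette yields ndG ≈ −0.15 (clears −0.1 but
not −0.2) and a 60-nt cassette ndG ≈ −0.25 to −0.34 (clears −0.2);
cassettes are redesigned at generation time until their duplex energy
clears a stability floor, so the planted edges are guaranteed rather
than probabilistic. Planted miRNA target sites carry one non-seed
mismatch, as natural sites do — which also keeps a site from doubling as
a spurious long duplex in the trans scan.

Counts are negative-binomial (variance μ + φμ², gamma–Poisson mixture;
Poisson at φ = 0) with expected count
`baseline_FPKM · 2^shift · exonic_length · depth / 10⁹`, the shift
(±log2fc, default 3) applied in the (tissue, deficient) cells the truth
table marks. Background baselines are log-normal (natural-log mean 3,
sigma 1.5), spanning low- to high-expression transcripts; up-regulated
plants start at 40 FPKM and down-regulated plants (classes I/III,
"highly expressed, down under deficiency") at 500 FPKM. The high
down-plant baseline follows the class definition and keeps the planted
mass from visibly distorting per-library FPKM normalization in a
90-transcript universe — in real libraries the changed transcripts are a
tiny mass fraction, and the generator preserves that property at desk
scale.

What the generator does **not** emulate: read-level noise (no FASTQ;
alignment/assembly are upstream of this artifact), multi-isoform genes,
positional biases, batch effects, and genuinely ambiguous positional
geometry. Passing the recovery tests therefore shows the pipeline's
logic is correct under its own assumptions, not that the thresholds are
optimal for any particular real dataset.

Problem sizes used by the test suite and the acceptance script — a
90-transcript annotated study, a 2,000-transcript expression-only
calibration study, 50 random classification fixtures of ≤ 200
transcripts, 200 short duplex pairs, and 100 shuffled eTM sets — were
chosen so the full validation runs in well under a minute while keeping
every planted category populated.

## Determinism and degenerate inputs

All randomness flows through one seed; stage outputs (tables sorted on
stable keys, fixed float formats) are byte-identical across same-seed
runs. The run report records wall-clock stage timings and is therefore
the one file excluded from byte-comparison; its counts are checked for
equality instead. Degenerate inputs are errors, not silent passes:
empty noise sets, fewer than two replicates, zero library sizes,
out-of-bounds exons, selections outside the enrichment universe, and
infeasible generator layouts all raise with named contexts.
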