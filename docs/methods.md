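# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and
the design decisions taken where the workflow left them open.

## Coordinates and record types

All genomic coordinates are 1-based inclusive (GFF3 convention); any
half-open arithmetic is internal to a function. When a gene carries
several mRNAs, the transcript with the longest total CDS is kept — the
usual one-model-per-gene convention for family surveys; the chosen rule
is visible in the pipeline report. Domain vocabularies are normalized
from Pfam accessions or model names onto a controlled set
(Lectin_legB/B_lectin/Lectin_C, kinase, TM, signal_peptide, EGF, PAN,
S_locus); `Pkinase` (PF00069) and `Pkinase_Tyr` (PF07714) both count as
kinase evidence. From HMMER `--domtblout` rows the per-domain
independent E-value is used, since the filter is a per-domain test.

## Identification filter

A protein is retained iff it has (i) at least one lectin-class hit with
E-value **strictly below** 0.001, (ii) at least one kinase hit, and
(iii) at least one TM hit. The cutoff applies only to the lectin hit;
kinase and TM need only be present, mirroring the two-stage practice of
a strict lectin HMM search followed by a permissive architecture
confirmation. The subfamily is decided by the lectin class of the
lowest-E-value hit; an exact tie between two lectin classes raises an
error rather than guessing, because in practice such cases are resolved
by manual inspection. Raising the cutoff can only grow the retained set
(a tested invariant).

## Sequence properties

Molecular weight uses average (not monoisotopic) residue masses plus one
water, reported in kDa (1 decimal in summaries) — the scale on which
such surveys print their tables. Unknown residues raise; optionally an
`X` may contribute a documented 110.0 Da placeholder. The isoelectric
point is the root of the Henderson–Hasselbalch net-charge function,
found by bisection on [0, 14] until the charge magnitude is below 1e-4
and the bracket is below 1e-6 pH units. The default pKa set is the flat
Bjellqvist/ExPASy table (N-term 7.5, C-term 3.55; K 10.0, R 12.0,
H 5.98; D 4.05, E 4.45, C 9.0, Y 10.0), configurable per call. The
table deliberately omits the terminal-residue pKa adjustments some
predictors apply; published pI values can therefore differ by roughly
±0.1–0.3, and pI figures should be compared for range plausibility, not
equality.

## Phylogeny

Distances are Poisson-corrected protein distances d = −ln(1 − p) with
pairwise deletion (columns gapped in either of the two rows are
ignored); p ≥ 1 or an empty comparison raises a saturation error. Trees
come from Saitou–Nei neighbor joining with the standard Q criterion;
ties in Q are broken by the smallest index pair so results are
deterministic. Negative branch estimates are clamped to zero with the
deficit moved to the sister branch, preserving the path length through
the new node (the MEGA-compatible convention). The output is unrooted
(one trifurcation). Bootstrap supports resample alignment columns with
replacement; the support of each internal bipartition of the full-data
tree is the percentage of replicate trees containing it. Replicates are
driven by a seeded generator, so supports are a deterministic function
of (alignment, n_reps, seed). Within a replicate, a saturated pair is
capped just below p = 1 (yielding a long branch) rather than discarding
the replicate, which would bias supports on noisy alignments.

For convenience the package includes an internal star multiple aligner:
every sequence is globally aligned (Needleman–Wunsch, BLOSUM62, gap
open 10, extend 0.5) to a center sequence — the longest, ties broken by
id — and merged on center coordinates with "once a gap, always a gap".
A star alignment was chosen over guide-tree progressive alignment
because the pairwise DP then runs entirely in compiled code and the
merge is linear in the number of sequences; for the intra-family
alignments this package targets (homologous, largely colinear proteins)
the difference is immaterial, and externally computed alignments are
accepted via FASTA whenever higher fidelity matters.

## Duplication detection, Ka/Ks and dating

Candidate duplicates are all unordered member pairs whose global protein
alignment has coverage **strictly greater** than 0.70 and identity
strictly greater than 0.70. "Similarity" is interpreted as percent
identity over aligned residue pairs (gap columns excluded), and the
coverage denominator is the longer sequence. A pair is tandem iff both
genes are on one chromosome, the distance between their nearest gene
boundaries is < 100 kb, and at most 5 annotated genes lie strictly
between them — counted strand-agnostically over the whole annotation,
since gene-order criteria in the literature do not condition on strand.
Everything else is dispersed; attribution of dispersed pairs to
segmental duplication vs ectopic movement is left to the user.

Ka/Ks follows classic NG86. Sites: at each codon position the fraction
of the three possible changes that are synonymous, summed over positions
and averaged between the two sequences; changes to stop codons count as
nonsynonymous, so every compared codon contributes exactly 3 sites split
between S and N (S + N = 3 × codons, a tested invariant). Differences:
averaged over all minimal mutational pathways between the two codons,
excluding pathways through stop codons (unless every pathway is
blocked, in which case all are used). Codons containing gaps or
ambiguity codes in either sequence, and aligned stop codons, are
skipped. Proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
d = −¾ ln(1 − 4p/3), undefined at p ≥ 3/4. The codon alignment is
projected from the protein alignment (terminal stops trimmed first;
internal stops are a hard error naming the sequence). ω = Ka/Ks is
flagged undefined when Ks = 0. Divergence time is T = Ks/2r in million
years; r defaults to 1.5e-8 synonymous substitutions per site per year
(the dicot clock) and is overridable. The implementation agrees exactly
with an independent NG86 implementation (Biopython `cal_dn_ds`) and
with an exhaustive pathway-enumeration oracle on small codon pairs;
both comparisons are kept as tests.

## Promoters

The promoter is the 1500 bp 5′ of the **translation start** (the first
CDS base), not the transcription start, because annotation-derived
surveys anchor there; minus-strand promoters are reverse-complemented so
the returned string always reads 5′→3′ toward the gene, and windows are
truncated with a warning at chromosome ends. Scanning is exact IUPAC
matching on both strands at every offset; overlapping occurrences are
all reported, and minus-strand hits are reported at the leftmost base of
the match on the promoter string. Web-service element catalogs are
replaced by a local TSV of named IUPAC patterns with a category column —
reproducible, offline and testable; position-weight-matrix scoring is
out of scope. The ubiquitous CAAT-box/TATA-box/TATC-box names are
excluded by default. Because "how many elements" can mean types or
instances, category summaries report both distinct element names and
occurrence counts, per gene and family-wide.

## Expression and qPCR

Thresholds are inclusive as conventionally printed: constitutive means
FPKM ≥ 1 in every tissue; a gene is in a tissue's Venn set when
FPKM ≥ 2 there. Venn regions are exact set algebra over 2–5 named sets;
region counts sum to the union size. The 3-group expression partition is
seeded k-means (100 restarts) on the per-gene mean of log₂(FPKM + 1),
with groups relabeled 1..3 by descending mean FPKM; k-means was chosen
because the high/mid/low structure such surveys describe is a 1-D
clustering problem and the seeded form is reproducible. A matrix of
identical genes degenerates to a single group with a warning.

qPCR analysis is 2^−ΔΔCT: per replicate ΔCt = Ct(target) −
Ct(reference); ΔΔCt = mean ΔCt(treatment) − mean ΔCt(control); the
p-value is a two-sided Welch (unequal-variance) t-test on the replicate
ΔCt values — Welch because replicate variances are not assumed equal.
Calls: up iff fold > 1 and p ≤ 0.05; down iff fold < 1 and p ≤ 0.05;
otherwise ns. Fold-changes are invariant to any constant added to a
replicate's Ct values (target and reference together), a tested
property. When both groups are numerically constant and equal, p is
reported as 1 rather than NaN.

## Synthetic data generator

The generator's defaults are the study conditions of the cucumber
LecRLK survey this workflow is modeled on: 46 members (23 G / 22 L /
1 C) distributed (7, 2, 12, 6, 6, 6, 7) over 7 chromosomes among decoy
and filler genes on both strands; CDS lengths uniform over 1803–2502 bp
with both endpoints planted; exon counts fixed so the family mean is
1.5 introns with a 9-exon maximum (the single C-type member carries 4
exons); G-type accessory architectures 10 EGF∧PAN / 5 PAN-only /
7 EGF-only / 1 neither; 25 members without signal peptides and 8 with
3 TM segments. Three duplicate pairs are planted at the synonymous
distances implied by T = 38.61, 30.96 and 32.35 MYA under r = 1.5e-8
(Ks ≈ 1.158, 0.929, 0.971) with ω = 0.08 — Ka low enough that the
pairs stay above the 70% protein-identity criterion, as real surviving
duplicates under purifying selection do. One pair is tandem with 2
intervening genes; the other two span chromosomes. The reported G-type
architecture tallies of the original survey sum to 24 over 23 G-type
genes; the generator uses 7 EGF-only so the total closes at 23.

Codon evolution is by site resampling, not a Markov chain: the
descendant receives at most one substitution per codon — synonymous
changes on the proportion pS = inv-JC(Ks) of synonymous sites,
nonsynonymous likewise — so the planted difference counts are analytic
and NG86 recovers them exactly. Because substitutions drift the
synonymous-site total, the planted counts are corrected iteratively
against the NG site counts of the evolved pair until difference counts
and averaged sites are consistent (at most 8 rounds; in practice 1–2).
Ancestral CDS draw amino acids uniformly and then a synonymous codon,
so proteins have balanced residue composition (uniform codon draws
would be strongly arginine-biased and push pI far above observed
ranges). The JC bound is enforced on the planted *proportion*
(p < 3/4), not the distance, so Ks values above 0.75 — as real
~30–40 MYA pairs have — are representable.

The FPKM matrix draws each gene log-normally (σ = 0.25 on the natural
log, mean-corrected) around its group mean (18.01 / 6.48 / 1.29 for
groups of 7 / 12 / 27) across 10 tissues, then plants: 3 silent genes,
5 tissue-specific genes (root ×2, cotyledon ×2, tendril), 2 genes with
one zero tissue, a sub-threshold dip tissue for the remaining low-group
genes, and 3 mid-group genes dipping in one Venn tissue — so the
constitutive count (17), the expressed-in-all-five-tissues count (16)
and all Venn placements have exact truth. Ct tables use a stable
reference (Ct ≈ 20), per-gene target baselines, and treatment shifts of
−log₂(fold) plus Gaussian noise (σ = 0.1 cycles, 3 biological
replicates). Planted response tallies per treatment are GA 5 up / 3
down, ABA 8/8 (including an 88-fold induction and a 17-fold
repression), NAA 6/14, IAA 1/8 (including a 5-fold repression), cold
0/4 — 20 up and 38 down events — with 15 genes responding to nothing.

What the generator does **not** emulate: realistic base composition,
isochores or intron-length distributions; codon-usage bias; alignment
difficulty (members are colinear, so the aligner is barely stressed);
correlated expression between tissues; reference-gene regulation; and
multi-hit codon evolution (at most one substitution per codon, which is
exactly why difference counts are analytic). Passing tests on synthetic
data therefore demonstrate correctness of the counting, clustering,
scanning and calling machinery under the stated models — not robustness
to divergent real-world data pathologies such as poorly alignable
N-terminal extensions or biased codon usage.

Two caveats follow from the noise model. With a 5% t-test and ~170
truly unchanged gene × treatment cells, the computed up/down tallies
run a few events above the planted 20/38 — the test's nominal false
positive rate, visible and expected. And the planted sub-threshold dips
pull the computed low-group mean (~0.95) below the generating mean
1.29.

## Problem sizes

The default synthetic family (46 members plus 35 decoys and 84 fillers)
is the package's standard demonstration size; the acceptance script
runs the full pipeline on it with 1000 bootstrap replicates and
20 × 500-codon Ks-recovery simulations per level. The test suite uses a
compact 8-member genome for pipeline-level tests and 25–200 bootstrap
replicates, sizes chosen to keep the suite quick while still exercising
every code path.

## Known limitations

- The star alignment can misplace residues around long indels; use an
  external aligner for publication-grade trees.
- NG86 with Jukes–Cantor correction underestimates Ks under strong
  transition/transversion bias or codon-usage bias; model-based
  estimators (e.g. YN00-style) are out of scope.
- The promoter scanner is exact-match IUPAC only; degenerate-matrix
  elements must be expressed as IUPAC consensus patterns.
- The 3-group partition assumes the family really has three expression
  levels; k is a parameter, not inferred.
- Tandem classification depends on annotation completeness: unannotated
  intervening genes inflate gap distances and deflate intervening
  counts.
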