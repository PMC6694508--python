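# Methods

This note records the models behind each stage, the parameters that matter,
and the choices made where the design was genuinely open.  It states no
number that the test suite or `scripts/acceptance.py` does not itself
compute.

## Study design being modelled

The pipeline targets a triploid interspecific hybrid and its two parents:
parent 1 contributes the An and Cn subgenomes, parent 2 contributes Ar, and
the F1 carries An + Ar + Cn.  An and Ar descend from a common A genome and
differ by a small per-site substitution rate; Cn has no counterpart in
parent 2.  Three biological replicates of one small-RNA library per sample
is the default replicate structure.

## Preprocessing

Adapter removal trims at the leftmost position where a prefix of the 3'
adapter matches with at most one mismatch per ten matched bases and at
least `min_overlap` (8) matched bases; trimmed inserts below 18 nt are
discarded, and 18–30 nt is the retained length window.  Quality filtering
discards reads with mean Phred below 20 (boundary inclusive) or any N;
both thresholds are package decisions, stated in the config.  ncRNA
filtering is exact-substring matching against the contaminant set on both
strands — deterministic and adequate at the scale the pipeline targets —
with the removal reason taken from the contaminant's class (rRNA, tRNA,
snRNA, snoRNA); a read ending in ≥8 consecutive A is removed as poly(A).
Counts are conserved by construction: input = low-quality + length-filtered
+ ncRNA/polyA + kept, per library.

## Hairpin folding and locus calling

Folding maximizes the number of nested base pairs (Watson–Crick plus G:U,
minimum loop 3) by dynamic programming; the traceback prefers closing the
outermost pair, which breaks co-optimal ties toward long contiguous stems.
Maximum pairing is used instead of free-energy minimization because every
acceptance criterion downstream needs only the pair set, and the optimum is
verifiable against exhaustive enumeration (the suite checks all-structure
enumeration for sequences up to 18 nt).

A candidate mature is a unique read with summed count ≥ `min_count` (5).
Each exact genome placement (multi-mapped reads, > 20 placements, are
excluded from locus calling) is tested for an enclosing hairpin by trying a
ladder of excision windows — 20 nt on one side and 20/50/100/150/250 nt on
the other, both orientations, tightest first, clipped to 60–300 nt.  The
ladder matters: with maximum-pairing folding, a 270 nt window whose tail is
~200 nt of unrelated sequence can fold the mature's arm into spurious
structure, so insisting on wide windows only would reject genuine loci.
The first window whose fold passes the criteria wins.

Acceptance criteria for a folded window (all configurable): mature length
18–26 nt; mature entirely on one arm — i.e. its paired bases must not point
in both directions, which is how straddling the terminal loop manifests;
≥14 mature bases paired; largest bulge inside the mature duplex ≤ 4 nt;
≥33 % of precursor bases paired.

Both arms of a perfectly complementary stem satisfy these criteria for the
same read, so catalogs contain mature-arm and star-arm placements of each
locus.  Without star-read evidence the arms are not distinguishable, and no
attempt is made to guess; all entity-level logic (presence, Venn, loss/
gain) keys on the mature sequence, which both placements share.

Conserved/novel classification: the distance between two matures is the
minimum over all ungapped offsets of substitutions in the overlap plus
overhanging bases; ≤2 against any known mature means conserved, with the
best-matching known (ties lexicographic) providing the family name after
stripping species prefix, variant letter and arm tag.

## Expression

TPM is count / library total × 10⁶.  The two-group test pools replicates
per side and conditions on the pooled total n = x_a + x_b: under Poisson
sampling the split is Binomial(n, N_a/(N_a+N_b)), and the two-sided p-value
sums all outcomes no more likely than the observed one.  Pooled counts are
overdispersed when biological replicates disagree, and the binomial split
is then anti-conservative; the conditional law of one negative binomial
given the sum of two is beta-binomial, so `de_contrast` estimates a common
NB dispersion across genes (pooled method of moments on the within-sample
replicate scatter, var = μ + φμ²) and uses the matched beta-binomial split
(α = p₀ν, β = (1−p₀)ν, ν = pooled replicate count / φ).  With φ = 0 the
test reduces exactly to the plain binomial, which remains the `de_test`
default and the form checked against exhaustive enumeration.  The suite
verifies type-I error ≤ 1.2 × nominal at α = 0.05 and 0.01 on 2 000 null
genes with dispersion 0.1 at mean 5 per replicate — the low-expression
regime where most miRNAs sit and where an exact test is the reason to
bother.

Differential calls require |log2FC| > 1 (strict), FDR < 0.001 and
P < 0.01, stated relative to the named control sample; log2FC uses a
0.5 TPM pseudocount to keep zero counts finite.  Benjamini–Hochberg is the
step-up procedure from statsmodels.  Sample similarity uses Pearson r and
Euclidean distance on log10(TPM+1) with average-linkage clustering — the
linkage is a package choice.  The comparative-CT helper is 2^−ΔΔCT.

## Non-additive expression

MPV is the arithmetic mean of the two parental TPM means (replicate means
first).  The F1 is non-additive when (F1+c)/(MPV+c) > 2 or < 0.5 — strict,
so a fold of exactly 2 stays additive — with P ≤ 0.05 from the exact test
of pooled F1 counts against the pooled parental counts over the summed
parental totals (whose rate is the additive expectation when library sizes
are comparable).  The plain-binomial form is used here: the fold-change
gate dominates the false-call rate, which the suite measures on a null
study.  Down-regulated calls are partitioned into parent1-higher /
parent2-higher / equal at |log2 ratio| > 1, a configurable operational
reading of "equal parental expression".  Loci absent from the hybrid (or
private to it) are structurally non-additive; truth-comparison logic
therefore excludes them from the additive/non-additive recovery checks.

## Homology and synteny

Homology search is ungapped seed-and-extend: diagonals sharing an exact
11-mer with the query are evaluated by aligning the full query at that
offset; a gene qualifies at ≥85 % identity over the full query or over the
best window covering ≥60 % of it, a precursor at ≥90 % over its full
length.  Hits rank by identity × coverage (ties by chromosome, position,
strand), top 5 kept.  At the divergence levels the pipeline targets (≤5 %)
a qualifying alignment always contains an exact 11-mer, so the seeded
search equals an exhaustive all-offset scan — the suite verifies this on a
20 kb fixture with planted diverged copies.

A miRNA's flank context is its ≤5 nearest protein-coding genes per side
(genes overlapping the locus go to the side of their midpoint).  For each
precursor placement, a flank counts as matched when one of its qualifying
hits overlaps an annotated coding gene within 100 kb of the placement; one
matched flank on either side makes the placement syntenic.  Set labels:
set1 — syntenic placement in the expected (same-lettered) subgenome; set2 —
syntenic only elsewhere; set3 — homology but no flank support; set4 — no
qualifying homology.  These four sets are this package's explicit
reconstruction of the classical 4-way synteny partition; the window and
thresholds are configurable and recorded in output metadata.  Lost = every
parental placement of a mature is set4 toward the F1; gained = every F1
placement is set4 toward both parents.  Aggregating per mature is what
makes homoeologous copies and star-arm placements behave as one entity.

## Target scoring

Ungapped antisense alignment at every offset; per miRNA position (1-based
from the 5' end): perfect pair 0, G:U 0.5, mismatch 1, doubled at positions
2–13; sites at or below 4.0 reported, best first, ties leftmost.  Bulged
duplexes and free-energy models are out of scope by design; the scheme is
the standard plant target penalty in its simplest auditable form.

## Synthetic data generator

What it emulates: per-site parental divergence (default 2 %) between An
and Ar; loci planted as constructive hairpins (5' arm containing the
mature, 6 nt loop, reverse-complemented arm — validity holds by
construction, no rejection sampling) at intergenic positions with ≥5 coding
genes per side; a home mixture of 55 % shared-A, 10 % An-only, 10 %
Ar-only, 25 % Cn loci; conserved matures drawn from a generated
miRBase-style known set with 0–2 substitutions, novel matures kept >2 from
every known; F1 losses excised from every homologous copy (coordinates
preserved by same-length random filler) and gains inserted as fresh
hairpins; true abundances log-uniform in [5, 500] per parent with the F1 at
MPV × 2^(±effect) for a chosen non-additive fraction; per-replicate counts
negative-binomial (Poisson as dispersion → 0); sequencing as a multinomial
of exactly `mean_depth` reads per library split into miRNA reads (with
per-base substitution errors), 24 nt genomic background (default fraction
0.4, which fixes the library length mode at 24 nt), and ncRNA contaminant
reads, a configurable fraction carrying the 3' adapter; constant Phred 35
qualities, as no quality model is part of the design.

What it does not emulate: repeat landscapes and multi-mapping families,
isomiRs, strand-biased or position-dependent error profiles, indels,
adapter dimers, degradation.  Passing recovery tests on this generator
therefore demonstrates the pipeline's logic, bookkeeping and statistics —
not robustness to every artefact of real libraries.

Default problem sizes (3 chromosomes × 100 kb per subgenome, 50 loci, 10⁵
reads per library) keep a full study, analysis included, around a minute on
one CPU; the desk-scale examples use half that.

## Numerical and degenerate-input conventions

Deterministic tie-breaks everywhere (lexicographic known ids, (chromosome,
position, strand) hit order, leftmost target site).  Zero-total libraries
normalize to all-zero TPM with a warning; both-sides-zero tests return
p = 1; zero-variance correlation returns a flagged undefined result rather
than NaN.  All randomness flows from one seeded Generator per stage;
identical seeds give byte-identical output files.

## Known limitations

Mismatch-tolerant read mapping is a quadratic scan intended for small
genomes (exact mapping, the default, is indexed); the homology/oracle
equality holds at moderate divergence, not adversarial mismatch spacing;
arm assignment of perfect stems is ambiguous by design; and the exact count
test models within-gene dispersion as common across genes, which is the
usual small-sample compromise.
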