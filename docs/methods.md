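# Methods

This note documents the statistical model behind `asmscope`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical and design
decisions a maintainer would want recorded.

## Data model and coordinates

The unit of evidence is one phased bisulfite read (`BisRead`): the base
called at the amplicon's index SNP plus an ordered vector of per-CpG
calls in {M, U, missing}. Reads are modeled post-alignment and
post-basecall (a documented TSV dialect), because the analysis begins at
phased calls; FASTQ/SAM handling, alignment and barcode demultiplexing
are upstream concerns and out of scope.

Coordinates are half-open, 0-based; interval length is `end − start` and
abutting intervals do not overlap (BED semantics). Printed genome-browser
coordinate pairs from the locus tables this package reproduces are
imported verbatim as `(start, end)`: their printed spans (e.g. the 225 bp
ELK3 DMR at chr12:96,617,249–96,617,474) equal the raw endpoint
difference, so no ±1 adjustment is applied. One printed locus is
internally inconsistent — the VTRNA2-1 region is described as "1.9 kb"
at chr5:135,414,670–135,416,821, whose difference is 2,151 bp; the
discrepancy is recorded here, not resolved.

## Allele-level methylation

Missing calls enter neither numerator nor denominator of any fraction.
Polymorphic CpGs (CpG-destroying/creating SNPs) are excluded from both
alleles' fractions, since apparent ASM there is sequence-driven; each
exclusion is logged. A read's methylated fraction is m/(m+u); an
allele's `mean_frac` is the unweighted mean of its reads' fractions
(clones weighted equally, not CpGs — matching per-clone percent
methylation), and pooled net methylation is the same mean over both
clone sets, which makes pooled net methylation exactly the
read-count-weighted mean of the two allele profiles.

Genotyping requires ≥10 usable reads with ≥20% minor-allele reads
(a tie at exactly 20% counts as heterozygous, since the rule is "at
least"). Reads whose SNP base matches neither declared allele are
discordant: excluded and logged. Net methylation requires ≥7 reads.
Multi-SNP amplicons phase on the declared index SNP only; within-amplicon
haplotype reconstruction is a non-goal.

## Per-sample ASM test

The two allele clone sets are compared by a two-sided Welch t-test on
per-read fractions. The source analysis specifies only "t-test"; Welch
was chosen because allele depths are routinely unequal after partition.
Significance requires p < 0.05 *and* ≥5 reads per allele. Degenerate
inputs (zero variance in both clone sets, or a clone set of one read)
bypass the t statistic: equal means give p = 1, separated means give
p = 0, both flagged. Calibration: under a null locus (both alleles at
0.5) at depth 30 the empirical per-sample significance rate is ≈0.05
(checked over 2,000 simulated loci).

## Heat-map aggregation and DMRs

Per amplicon × tissue: `hom_all` when no sample is het; `stippled_grey`
when no sample reaches read depth 10; otherwise the cell carries the
mean of |Δ| over het samples. `solid_red` requires mean |Δ| ≥ 0.30, ≥2
het samples and at least half individually significant — "less than
half" excludes exactly half, so half counts as sufficient. `stippled_red`
is the same contrast with only one het sample or a minority significant.
|Δ| rather than signed Δ is averaged because the hypermethylated
nucleotide legitimately swaps between samples at imprinted loci; sign
concordance is assessed by the mode classifier, not the heat map. The
cell emits the raw mean |Δ| (the display scale 0.30–1 is a plotting
concern).

DMRs are maximal runs of red cells per tissue, merged across tissues
when they share an amplicon; the DMR interval spans first to last member
amplicon. Boundary refinement below amplicon resolution is a non-goal.

## Imprinted vs haplotype-dependent classification

Parental origin of each offspring allele is assigned iff exactly one
labelling is Mendelian-consistent (verified exhaustively against
enumeration over all 27 unordered biallelic genotype triples);
inconsistent trios are excluded and counted. Imprinting is tested by a
df = 1 chi-square goodness-of-fit of the (maternal, paternal) hyper
counts against 50:50 **without continuity correction**: this exactly
reproduces p = 0.000311 at counts (13, 0) and p = 0.001565 at (10, 0),
whereas a Yates-corrected statistic gives 0.000875 and is therefore the
wrong variant. The p-value equals erfc(√(χ²/2)) for df = 1.

Cohort concordance is the fraction of significantly ASM het samples
sharing the majority hypermethylated nucleotide, tested against 0.5 by a
two-sided exact binomial. The verdict rules:

- `none` when no tissue cell is red;
- `haplotype_dependent` when the binomial test rejects chance and
  concordance ≥ 0.90 (the floor is a package choice, config-exposed; the
  motivating loci were fully concordant);
- `imprinted_<parent>` when the trio chi-square rejects with ≥3
  informative trios (df = 1 chi-square is unreliable below that;
  config-exposed) *and* cohort concordance is consistent with chance;
- `ambiguous` otherwise, including conflicting strong evidence.

Tissue-specific ASM is classified per tissue, with the tissue attached
to the verdict. With ~10 het samples, an imprinted locus draws a
concordant-by-chance cohort (≥9/10 one allele) about 2% of the time and
is then misclassified or ambiguous; this bounds classifier accuracy near
97–98%, consistent with the measured ≥95% per-mode recovery.

Reciprocal-cross decomposition computes strain (CAST − B6) and parent
(maternal − paternal) mean differences within each cross direction and
averages the two directions, which cancels the strain/parent
confounding; per-factor Welch t-tests run on per-clone values. One
direction alone is refused as confounded.

## Genome-scale CpG classes and CTCF enrichment

Class boundaries are exactly as printed: fully methylated is strictly
>90% of reads, unmethylated strictly <10%, partial the closed band
[10%, 90%] — a CpG at exactly 90% is partial. ASM status is an input
flag (defined upstream by the whole-genome bisulfite analysis being
consumed); an internal flagger exists for simulations only. CpGs at
polymorphic sites are excluded from enrichment by default (toggleable),
since CpG-SNPs mimic ASM.

Context labels: promoter = within 1 kb of a TSS; CGI = within 250 bp of
an island; promoter-CGI = both; intragenic = in a gene body and not
promoter; intergenic otherwise. CTCF proximity = any peak intersecting a
500 bp CpG-centred window, over the union of supplied peak sets. Peak
"center" for the 1 kb ASM-CpG window is the interval midpoint (no
summit definition is given upstream); summit columns are honored when
present. Qualifying ASM-CTCF sites need ≥2 ASM CpGs in the half-open
1 kb window. Gene association uses interval gap distance ≤100 kb; a
"same haplotype block" call requires one block to contain the peak, ≥1
of its ASM CpGs and ≥1 GWAS SNP at p ≤ 1e-6.

Enrichment is a one-sided Fisher exact test (ASM more often near CTCF)
per context stratum and per comparison class; the odds ratio is reported
with a Haldane 0.5 correction for display only, never for the p-value.
Degenerate margins yield p = 1 with a flag. The implementation is
validated against an exact integer hypergeometric-tail oracle
(`math.comb` arithmetic): exhaustively over all 2×2 tables with total
≤30 plus a 2,000-table random sample with totals up to 200, agreeing to
<1e-10. Full enumeration of every table to N = 200 (~7×10⁷ tables) is
not attempted; the exhaustive-small plus randomized-large design covers
the same range. "Fold increase" ambiguity (percentages vs odds) is
sidestepped by reporting class-member percentages near CTCF alongside
the Fisher p.

The headline genome-scale counts of the motivating study (13,485 CTCF
sites, 158 ASM-CTCF sites, 40.4% promoter-CGI fraction, 1.7-fold) depend
on external H1 hES data and are not reproduced at desk scale; the module
is validated by oracle equivalence and planted-truth recovery instead.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design's observable structure:
phased amplicon reads at mean depth 90 per sample per amplicon, ≥4 CpGs
per amplicon, index SNPs at heterozygosity up to 0.5 drawn under
Hardy–Weinberg; imprinted loci (maternal or paternal copy
hypermethylated regardless of base), haplotype-dependent loci (fixed
nucleotide hypermethylated), null loci, and tissue-restricted ASM
(placenta-only scenarios); trios with fair Mendelian transmission;
reciprocal crosses with additive strain/parent shifts clamped to [0,1];
and genome-scale per-CpG count tables in a tiled synthetic geography
(one CpG per 10 kb tile, so context annotations cannot interfere), with
class proportions defaulting to the reference whole-genome analysis this
table emulates (ASM 15.4%, full 39.0%, partial 45.3%, unmethylated
0.35% of 514,181 CpGs).

Default allelic contrast is 0.90 vs 0.05 (Δ = 0.85), matching the
strong ASM of the motivating loci. Noise is per-call: bisulfite
conversion failure (true U reads M) at 0.005 and sequencing error (any
call flips; SNP base replaced by a random other base) at 0.001 — the
platforms' conversion efficiency is not stated anywhere authoritative,
so these are plausible, config-exposed placeholders. Conversion failure
is modeled per CpG call, not per molecule; molecule-level correlation,
454 homopolymer error structure and PCR duplicates are not modeled.
Passing tests therefore demonstrate correctness of the inference chain
under idealized read-level noise, not robustness to platform-specific
artifacts.

The planted-enrichment recovery scenario oversamples the promoter-CGI
stratum (60% of CpGs, ASM fraction 25%) so that a planted odds ratio of
2 at 5,000 CpGs is decisively detectable; it is a stylized power
scenario, not a genome portrait. Detection uses a Bonferroni-style
threshold of 1e-4 (0.05 spread over the ~500 stratum tests of a 20-run
sweep) so the family-wise false-positive rate across non-planted strata
stays negligible while power at the planted effect remains ample.
Null-calibration of the enrichment stage uses the ASM-vs-full and
ASM-vs-partial comparisons; the unmethylated class is too rare (~17
CpGs per 5,000) for a calibrated test and is excluded from the
false-positive rate.

Calibration problem sizes — 2,000 null loci at depth 30; 200 replicates
for power and DMR recovery; 200 loci per classifier mode with 20
unrelated individuals (≈10 hets) and 25 trios (≈9 informative); 20
genome-scale runs of 5,000 CpGs — were chosen once so the whole sweep
completes in minutes on one core while keeping Monte-Carlo error well
inside the asserted bands.

## MSNP screen

The screen operates at the genotype-call level: a candidate is an AB
call in the undigested preparation converting to AA/BB under HpaII,
recurrent in ≥2 samples. An MspI NoCall supports the candidate (the
fragment demonstrably contains cut sites); an MspI call remaining AB is
recorded as a caution rather than an exclusion, because the original
screen resolved such cases by manual inspection of probe-level
hybridization, which has no faithful automated surrogate. Raw array
intensity processing is out of scope; calls are the input contract.

## Primer design

Templates are both strands of the bisulfite-converted genome: non-CpG
C → T, CpG C → the ambiguity code Y, SNP positions with heterozygote
frequency >1% masked to N. Constraints are enforced as printed: Tm
56–60 °C, GC 35–65%, ≤1 CpG per primer (0 preferred), product
200–650 bp (200–450 preferred), structure Tm ≤ 46 °C, no off-target
product of 50–2000 bp with ≤2 mismatches per primer. "Preferred" bands
are implemented as ranking keys, not hard filters.

Numerical choices: Tm is nearest-neighbor thermodynamics at 50 mM
monovalent salt and 250 nM primer (no model is named upstream; the model
and conditions are config-exposed since absolute Tm windows shift with
them); Y codes are evaluated as T (fully converted template). Secondary
structure is approximated by the melting temperature of the
maximal-complementarity contiguous duplex between the two sequences
(self, cross and hairpin collapse to this proxy; full folding is out of
scope). The off-target scan emulates reverse e-PCR: both primers are
scanned in both orientations against both converted strands, a binding
site requires ≤2 mismatches with an exact 3′-terminal base (the
3′-anchoring assumption is flagged — the upstream screen does not state
it), and any non-target product in 50–2000 bp fails the pair. Candidate
pairs are restricted to those bracketing the region's CpG/SNP core,
which is also what selection requires (≥4 CpGs and a het ≥0.2 SNP
between the primers). The pipeline uses no randomness; re-runs are
byte-identical.

## Known limitations

- Amplicon-resolution DMR boundaries only; no per-CpG smoothing.
- Single-index-SNP phasing; no multi-amplicon haplotype extension.
- The classifier's imprinting call needs trio data; unrelated cohorts
  alone cannot distinguish imprinted from rare-haplotype ASM.
- The enrichment stage consumes ASM flags; it does not re-derive ASM
  from genome-scale allele counts (an internal flagger exists for
  simulation only).
- Secondary-structure screening is a duplex proxy, not a folding model.
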