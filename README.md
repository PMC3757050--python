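# asmscope

Allele-specific DNA methylation (ASM) analysis from phased bisulfite
amplicon reads.

## The problem

At some loci the two alleles of a locus carry systematically different CpG
methylation within one sample. Two mechanisms produce this asymmetry:

- **Imprinted ASM** — methylation dictated by parental origin: the
  maternal (or paternal) allele is hypermethylated regardless of which
  nucleotide it carries.
- **Haplotype-dependent ASM** — methylation dictated by the local DNA
  sequence: the *same* nucleotide allele is hypermethylated in every
  heterozygous carrier.

Distinguishing the two, delimiting the differentially methylated region
(DMR), and relating ASM to CTCF insulator binding and GWAS haplotypes is
the core analysis task of ASM mapping studies. `asmscope` implements that
analysis chain as a tested, reusable library for epigenomics researchers
working with long-read bisulfite amplicon data (where each read carries an
index-SNP base call plus a per-CpG methylation vector, giving complete
phase with no ambiguity).

## What it computes

Given phased reads grouped per sample and amplicon, with index SNP of
alleles $a/b$:

- **Genotyping** — a sample is het iff it has ≥10 usable reads with ≥20%
  carrying the minor allele.
- **Per-sample ASM** — reads split by allele; per-read methylated
  fractions $f_i = m_i/(m_i+u_i)$ compared between the two clone sets by
  a Welch $t$-test; the allelic contrast is
  $\Delta = \bar f_a - \bar f_b$, significant when $p < 0.05$ with ≥5
  reads per allele.
- **Heat-map aggregation** — per amplicon × tissue, cells are colored by
  mean $|\Delta|$ over het samples: *solid red* when mean $|\Delta| \ge
  0.30$ with ≥2 het samples and ≥ half individually significant,
  *stippled red* for the same contrast on weaker support, with further
  categories for all-homozygous and low-depth cells; runs of red cells
  delimit DMRs at amplicon resolution.
- **Mode classification** — across unrelated het carriers, concordance of
  the hypermethylated nucleotide is tested against 0.5 (exact binomial);
  in parent-offspring trios, the maternal:paternal counts of the
  offspring's hypermethylated allele are tested against 50:50 with a
  df = 1 chi-square goodness-of-fit test (no continuity correction):
  $\chi^2 = \sum (O-E)^2/E$, upper-tail $p$. Reciprocal inter-strain
  crosses decompose allele methylation into additive strain and
  parent-of-origin effects.
- **Genome-scale CTCF co-localization** — CpGs classified as ASM / fully
  methylated (>90% reads) / partial (10–90%) / unmethylated (<10%),
  annotated by genomic context (promoter ±1 kb of TSS, CGI ±250 bp,
  intragenic, intergenic), flagged for CTCF peaks in a 500 bp CpG-centred
  window, and tested per stratum by one-sided Fisher exact tests; CTCF
  peaks with ≥2 ASM CpGs in a 1 kb window are cross-tabulated to genes
  (≤100 kb), GWAS SNPs ($p \le 10^{-6}$) and haplotype blocks.
- **MSNP screening** — candidate ASM loci from SNP-array call conversions
  (AB undigested → AA/BB after HpaII pre-digestion) recurring in ≥2
  samples.
- **Primer design** — bisulfite-PCR panels against an in-silico
  converted, SNP-masked genome under the full printed constraint set
  (Tm 56–60 °C, GC 35–65%, ≤1 CpG per primer, product 200–650 bp,
  duplex/hairpin Tm ≤ 46 °C, no 50–2000 bp off-target with ≤2 mismatches,
  ≥4 CpGs and a het ≥ 0.2 SNP between the primers).

A synthetic-data generator (`asmscope.simdata`) emulates every input —
phased amplicon reads with conversion failure and sequencing error,
trios, reciprocal crosses, and genome-scale CpG/CTCF tables — with ground
truth attached, so every stage is validated by planted-truth recovery.

## Worked example

Simulate a haplotype-dependent locus (20 individuals, depth 90) and run
the classification chain:

```sh
$ asmscope simulate --mode haplotype_dependent --n-individuals 20 \
      --depth 90 --seed 11 --out sim20.tsv
wrote 1800 reads to sim20.tsv (seed=11)

$ asmscope asm-call sim20.tsv --snp rsSIM:chrS:10005:A:G \
      --amplicon amp1:chrS:10000:10124 --out heatmap.tsv

$ asmscope classify sim20.tsv --snp rsSIM:chrS:10005:A:G
{
  "mode": "haplotype_dependent",
  "concordance": 1.0,
  "binomial_p": 0.00048828125,
  ...
}
```

Every heterozygous sample showed the same hypermethylated nucleotide
(concordance 1.0 over 12 het carriers; the exact binomial test against
chance gives $p = 2 \cdot 2^{-12} \approx 0.00049$), so the locus is
called haplotype-dependent. The heat-map cell for this amplicon reads
`solid_red:0.84:1.0000:12` — a mean allelic methylation difference of
0.84 over 12 het samples, all individually significant.

For trio evidence of imprinting, the chi-square test on parent-of-origin
counts reproduces the canonical values directly:

```python
>>> from asmscope.mode_classifier import score_imprinting_counts
>>> score_imprinting_counts(13, 0)   # 13 trios, all maternal-hyper
(13.0, 0.000311..., 'maternal')
>>> score_imprinting_counts(10, 0)
(10.0, 0.001565..., 'maternal')
```

## Layout

| module | role |
| --- | --- |
| `asmscope.core_model` | intervals, SNP/CpG types, threshold registry |
| `asmscope.io_formats` | read-table / heat-map TSV dialects, BED tracks, config |
| `asmscope.simdata` | synthetic reads, trios, crosses, genome-scale tables |
| `asmscope.allele_methylation` | genotyping, allele partitioning, profiles |
| `asmscope.asm_stats` | per-sample tests, heat-map cells, DMR delineation |
| `asmscope.mode_classifier` | imprinted vs haplotype-dependent verdicts |
| `asmscope.ctcf_enrichment` | CpG classes, context strata, Fisher tests, GWAS |
| `asmscope.msnp_screen` | SNP-array call-conversion screen |
| `asmscope.amplicon_design` | bisulfite primer panel design |
| `asmscope.calibration` | planted-truth recovery and calibration sweeps |

See `docs/methods.md` for the statistical model, parameter defaults, and
known limitations.
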