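"""End-to-end calibration and planted-truth recovery experiments.

Each function sets up a simulated dataset with known ground truth via
:mod:`asmscope.simdata`, runs the corresponding pipeline stage, and
returns summary statistics: type-I error of the per-sample ASM caller,
power of the heat-map/DMR stage at the study's allelic contrast, verdict
accuracy of the imprinting/haplotype classifier, agreement of the Fisher
machinery with an exact enumeration oracle, recovery of a planted
CTCF-enrichment signal, and constraint soundness of the primer designer.

Problem sizes are chosen so a full sweep runs in minutes on one core:
2,000 null loci at depth 30 for caller calibration, 200 replicates for
power and DMR recovery, 200 loci per mode for the classifier, 5,000-CpG
genome-scale tables over 20 replicate runs, and a 20 kb toy genome for
design.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from . import amplicon_design as ad
from .allele_methylation import call_sample_genotype, net_methylation, split_reads_by_allele
from .asm_stats import AsmResult, asm_test_sample, build_call_matrix, delineate_dmr
from .core_model import GenomicInterval, SnpVariant, Thresholds
from .ctcf_enrichment import build_cpg_records, enrichment_tables
from .mode_classifier import (
    analyze_trios,
    classify_locus,
    score_haplotype_dependence,
    score_imprinting,
)
from .simdata import (
    LocusScenario,
    make_scenario,
    simulate_locus,
    simulate_trio_cohort,
    simulate_wgbs_table,
)

__all__ = [
    "fisher_one_sided_oracle",
    "fisher_oracle_deviation",
    "null_asm_calibration",
    "asm_power_and_dmr_recovery",
    "classifier_recovery",
    "planted_enrichment_recovery",
    "null_enrichment_fp_rate",
    "mendelian_exhaustive_check",
    "toy_design_genome",
    "primer_design_soundness",
]


# ---------------------------------------------------------------------------
# Fisher exact: exhaustive hypergeometric tail oracle

def fisher_one_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p for the 2×2 table [[a,b],[c,d]] by
    exact integer hypergeometric tail summation: P(X ≥ a) for X drawn
    from Hypergeom(N, a+b, a+c) — independent of any library routine."""
    r1, r2, c1 = a + b, c + d, a + c
    n_total = r1 + r2
    num = sum(comb(r1, k) * comb(r2, c1 - k) for k in range(a, min(r1, c1) + 1))
    return num / comb(n_total, c1)


def fisher_oracle_deviation(
    max_exhaustive_n: int = 30,
    n_random: int = 2000,
    max_random_n: int = 200,
    seed: int = 0,
) -> tuple[float, int]:
    """Max |implementation − oracle| over all 2×2 tables with total up to
    ``max_exhaustive_n`` plus a random sample of larger tables up to
    ``max_random_n``.  Returns (max deviation, number of tables checked)."""
    worst = 0.0
    n_checked = 0

    def check(a: int, b: int, c: int, d: int) -> None:
        nonlocal worst, n_checked
        impl = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
        worst = max(worst, abs(impl - fisher_one_sided_oracle(a, b, c, d)))
        n_checked += 1

    for total in range(1, max_exhaustive_n + 1):
        for a in range(total + 1):
            for b in range(total - a + 1):
                for c in range(total - a - b + 1):
                    check(a, b, c, total - a - b - c)
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        total = int(rng.integers(max_exhaustive_n + 1, max_random_n + 1))
        cuts = np.sort(rng.integers(0, total + 1, size=3))
        a, b, c = int(cuts[0]), int(cuts[1] - cuts[0]), int(cuts[2] - cuts[1])
        check(a, b, c, total - a - b - c)
    return worst, n_checked


# ---------------------------------------------------------------------------
# ASM caller calibration and power

def null_asm_calibration(
    n_loci: int = 2000,
    depth: int = 30,
    n_individuals: int = 4,
    seed: int = 0,
    th: Thresholds | None = None,
) -> tuple[float, int]:
    """Fraction of per-sample ASM t-tests called significant under the
    null (both alleles at methylation 0.5), among heterozygous samples
    with ≥5 reads per allele.  Returns (rate, number of tests)."""
    th = th or Thresholds()
    rng = np.random.default_rng(seed)
    scenario = make_scenario("null", meth_p_hyper=0.5, meth_p_hypo=0.5)
    n_sig = n_tests = 0
    for _ in range(n_loci):
        table, _ = simulate_locus(
            scenario, n_individuals, depth_per_amplicon=depth, rng=rng
        )
        for reads in table.by_sample().values():
            gt = call_sample_genotype(reads, scenario.snp, th)
            if gt.status != "het":
                continue
            ra, rb, _ = split_reads_by_allele(reads, scenario.snp)
            if min(len(ra), len(rb)) < th.asm_min_reads_per_allele:
                continue
            res = asm_test_sample(ra, rb, th, alleles=scenario.snp.alleles)
            n_tests += 1
            n_sig += res.significant
    return n_sig / n_tests, n_tests


def _simulate_het_panel(
    scenario: LocusScenario,
    n_het: int,
    depth: int,
    rng: np.random.Generator,
    th: Thresholds,
    max_individuals: int = 30,
):
    """Reads for a cohort containing exactly ``n_het`` heterozygous
    samples (plus any homozygous samples drawn along the way)."""
    table, _ = simulate_locus(scenario, max_individuals, depth_per_amplicon=depth, rng=rng)
    kept: dict = {}
    hets = 0
    for key, reads in sorted(table.by_sample().items()):
        gt = call_sample_genotype(reads, scenario.snp, th)
        if gt.status == "het":
            if hets >= n_het:
                continue
            hets += 1
        kept[key] = reads
    return kept


def asm_power_and_dmr_recovery(
    n_reps: int = 200,
    depth: int = 90,
    n_het: int = 5,
    seed: int = 0,
    th: Thresholds | None = None,
) -> dict[str, float]:
    """Recovery of a planted ASM amplicon flanked by null amplicons.

    Each replicate simulates a 3-amplicon panel — a haplotype-dependent
    locus at allelic contrast Δ = 0.85 (0.90 vs 0.05) between two null
    amplicons — with ``n_het`` heterozygous samples at the given depth,
    then asks whether the heat-map cell at the planted amplicon is
    solid_red, whether any flanking cell is falsely red, and whether the
    delineated DMR matches the planted amplicon within one amplicon.
    """
    th = th or Thresholds()
    rng = np.random.default_rng(seed)
    n_solid = n_false_red = n_dmr_ok = 0
    for _ in range(n_reps):
        reads_by_sample: dict = {}
        amplicons = []
        for i, mode in enumerate(("null", "haplotype_dependent", "null")):
            scenario = make_scenario(mode, start=10_000 + 2_000 * i, amplicon_id=f"amp{i}")
            amplicons.append((f"amp{i}", scenario.amplicon.interval, scenario.snp))
            reads_by_sample.update(
                _simulate_het_panel(scenario, n_het, depth, rng, th)
            )
        matrix = build_call_matrix(reads_by_sample, amplicons, th)
        planted = matrix.cell("amp1", "PBL").category
        flank_red = any(
            matrix.cell(a, "PBL").category in ("solid_red", "stippled_red")
            for a in ("amp0", "amp2")
        )
        n_solid += planted == "solid_red"
        n_false_red += flank_red
        dmrs = delineate_dmr(matrix)
        if len(dmrs) == 1 and set(dmrs[0].amplicon_ids) <= {"amp0", "amp1", "amp2"}:
            ids = dmrs[0].amplicon_ids
            n_dmr_ok += "amp1" in ids and len(ids) <= 2
    return {
        "solid_red_rate": n_solid / n_reps,
        "flank_false_red_rate": n_false_red / n_reps,
        "dmr_within_one_amplicon_rate": n_dmr_ok / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Mode classifier recovery

def _classify_one_locus(
    mode: str,
    rng: np.random.Generator,
    th: Thresholds,
    n_unrelated: int = 20,
    n_trios: int = 25,
    depth: int = 90,
):
    scenario = make_scenario(mode)
    table, _ = simulate_locus(scenario, n_unrelated, depth_per_amplicon=depth, rng=rng)
    het_results: dict[str, AsmResult] = {}
    genotypes = []
    hom_net: dict[str, list[float]] = {}
    results = []
    for (_, _, sample_id), reads in sorted(table.by_sample().items()):
        gt = call_sample_genotype(reads, scenario.snp, th)
        genotypes.append(gt)
        if gt.status == "het":
            ra, rb, _ = split_reads_by_allele(reads, scenario.snp)
            if min(len(ra), len(rb)) == 0:
                continue
            res = asm_test_sample(
                ra, rb, th, sample_id=sample_id, alleles=scenario.snp.alleles
            )
            het_results[sample_id] = res
            results.append(res)
        elif gt.status in ("hom_a", "hom_b"):
            allele = scenario.snp.allele_a if gt.status == "hom_a" else scenario.snp.allele_b
            net = net_methylation(reads, th)
            if net is not None:
                hom_net.setdefault(allele, []).append(net)
    from .asm_stats import aggregate_tissue

    cell = aggregate_tissue("amp1", scenario.tissues[0], results, genotypes, th)
    asm_present = cell.category in ("solid_red", "stippled_red")
    haplo = score_haplotype_dependence(
        het_results, {a: float(np.mean(v)) for a, v in hom_net.items()}
    )
    trio_table, pedigree, _ = simulate_trio_cohort(
        scenario, n_trios, depth_per_amplicon=depth, rng=rng
    )
    reads_by_ind: dict = {}
    for read in trio_table.reads:
        reads_by_ind.setdefault(read.individual_id, []).append(read)
    trio_results, _ = analyze_trios(reads_by_ind, pedigree, scenario.snp, th)
    trio_ev = score_imprinting(trio_results)
    return classify_locus(haplo, trio_ev, th, asm_present=asm_present)


def classifier_recovery(
    modes: tuple[str, ...] = ("imprinted_maternal", "haplotype_dependent", "null"),
    n_loci: int = 200,
    seed: int = 0,
    th: Thresholds | None = None,
) -> dict[str, float]:
    """Verdict accuracy per simulated mode, judged against the generator's
    ground truth.  A null locus is correct when classified ``none``; the
    ASM modes are correct only under the exactly matching verdict."""
    th = th or Thresholds()
    rng = np.random.default_rng(seed)
    acc = {}
    for mode in modes:
        expected = "none" if mode == "null" else mode
        n_ok = 0
        for _ in range(n_loci):
            cls = _classify_one_locus(mode, rng, th)
            n_ok += cls.mode == expected
        acc[mode] = n_ok / n_loci
    return acc


# ---------------------------------------------------------------------------
# CTCF enrichment recovery

#: stylized genome-scale scenario for the planted-enrichment recovery run:
#: the promoter-CGI stratum is oversampled so the planted odds ratio of 2
#: is decisively detectable at 5,000 CpGs.
PLANTED_CONTEXT_MIX = {
    "promoter_cgi": 0.60,
    "promoter": 0.10,
    "cgi": 0.10,
    "intergenic": 0.10,
    "intragenic": 0.10,
}
PLANTED_CLASS_MIX = {"asm": 0.25, "full": 0.45, "partial": 0.29, "unmeth": 0.01}

#: Bonferroni-style detection threshold controlling the family-wise
#: false-positive rate across all strata and replicate runs (0.05 / 500)
DETECTION_ALPHA = 1e-4

_EXCLUSIVE_STRATA = ("intergenic", "intragenic", "promoter", "cgi", "promoter_cgi")


def _exclusive_stratum(context: frozenset[str]) -> str:
    if "promoter_cgi" in context:
        return "promoter_cgi"
    for label in ("promoter", "cgi", "intragenic", "intergenic"):
        if label in context:
            return label
    return "intergenic"


def _stratified_fisher(records, comparison: str = "full") -> dict[str, float]:
    """One-sided ASM-vs-``comparison`` Fisher p per *exclusive* context
    stratum (each CpG counted in exactly one stratum)."""
    groups: dict[str, list] = {s: [] for s in _EXCLUSIVE_STRATA}
    for r in records:
        groups[_exclusive_stratum(r.context)].append(r)
    out = {}
    for label, recs in groups.items():
        stratum_key = label if label != "promoter_cgi" else "promoter_cgi"
        res = enrichment_tables(recs, strata=(stratum_key,), comparisons=(comparison,))
        out[label] = res[0].fisher_p if res and not res[0].degenerate else 1.0
    return out


def planted_enrichment_recovery(
    n_runs: int = 20,
    n_cpgs: int = 5000,
    odds_ratio: float = 2.0,
    seed: int = 0,
    th: Thresholds | None = None,
) -> dict[str, float]:
    """Detect a planted promoter-CGI ASM-CTCF enrichment, and nowhere else.

    Per replicate run, a genome-scale table with the planted odds ratio is
    simulated, CpGs are classified/annotated from the emitted tracks, and
    the ASM-vs-full Fisher test is run per exclusive stratum.  A run
    succeeds when the promoter-CGI stratum is detected at the family-wise
    threshold and no other stratum is.
    """
    th = th or Thresholds()
    rng = np.random.default_rng(seed)
    n_detected = n_exclusive = 0
    for _ in range(n_runs):
        counts, peaks, genes, cgis, _ = simulate_wgbs_table(
            n_cpgs,
            class_mix=PLANTED_CLASS_MIX,
            ctcf_density=0.35,
            planted_promoter_cgi_enrichment=odds_ratio,
            context_mix=PLANTED_CONTEXT_MIX,
            rng=rng,
        )
        records = build_cpg_records(counts, peaks, genes, cgis, th)
        pvals = _stratified_fisher(records)
        hit = pvals["promoter_cgi"] < DETECTION_ALPHA
        others = [v for k, v in pvals.items() if k != "promoter_cgi"]
        clean = all(v >= DETECTION_ALPHA for v in others)
        n_detected += hit
        n_exclusive += hit and clean
    return {
        "detected_rate": n_detected / n_runs,
        "detected_exclusively_rate": n_exclusive / n_runs,
        "n_runs": n_runs,
    }


def null_enrichment_fp_rate(
    n_runs: int = 20,
    n_cpgs: int = 5000,
    seed: int = 0,
    th: Thresholds | None = None,
) -> tuple[float, int]:
    """Fraction of stratum-level Fisher tests significant at 0.05 when no
    enrichment is planted (ASM-vs-full and ASM-vs-partial comparisons;
    the unmethylated class is too rare at this scale for a calibrated
    test).  Returns (rate, number of tests)."""
    th = th or Thresholds()
    rng = np.random.default_rng(seed)
    n_sig = n_tests = 0
    for _ in range(n_runs):
        counts, peaks, genes, cgis, _ = simulate_wgbs_table(
            n_cpgs, ctcf_density=0.30, planted_promoter_cgi_enrichment=1.0, rng=rng
        )
        records = build_cpg_records(counts, peaks, genes, cgis, th)
        for comparison in ("full", "partial"):
            for p in _stratified_fisher(records, comparison=comparison).values():
                n_tests += 1
                n_sig += p < 0.05
    return n_sig / n_tests, n_tests


# ---------------------------------------------------------------------------
# Mendelian oracle

def mendelian_exhaustive_check() -> tuple[int, int]:
    """Compare parental-origin inference against brute-force enumeration
    over all 27 unordered biallelic genotype triples.

    Returns (number agreeing, total).  The oracle enumerates both
    labellings of the offspring alleles and checks Mendelian consistency
    directly; agreement requires matching status and, for assigned
    triples, a maternal allele carried by the mother and a paternal
    allele carried by the father reconstructing the offspring genotype.
    """
    from itertools import combinations_with_replacement

    from .mode_classifier import infer_parental_origin

    gts = list(combinations_with_replacement(("A", "G"), 2))
    n_ok = total = 0
    for m in gts:
        for f in gts:
            for child in gts:
                total += 1
                labellings = {
                    (x, y)
                    for (x, y) in ((child[0], child[1]), (child[1], child[0]))
                    if x in m and y in f
                }
                call = infer_parental_origin(m, f, child)
                if not labellings:
                    ok = call.status == "mendelian_error"
                elif len(labellings) == 2:
                    ok = call.status == "uninformative"
                else:
                    (mat, pat) = next(iter(labellings))
                    ok = (
                        call.status == "assigned"
                        and call.maternal_allele == mat
                        and call.paternal_allele == pat
                        and call.maternal_allele in m
                        and call.paternal_allele in f
                        and tuple(sorted((call.maternal_allele, call.paternal_allele)))
                        == tuple(sorted(child))
                    )
                n_ok += ok
    return n_ok, total


# ---------------------------------------------------------------------------
# Primer design soundness

def toy_design_genome(
    seed: int = 0, length: int = 20_000
) -> tuple[dict[str, str], list[SnpVariant], dict[str, list[int]], list[GenomicInterval]]:
    """A 20 kb single-chromosome toy genome with three engineered target
    regions, each carrying a CpG/SNP-rich core between G-rich primer
    shoulders, plus common SNPs elsewhere to exercise masking.

    Returns (genome, snps, cpg positions per chrom, target regions).
    """
    rng = np.random.default_rng(seed)
    # background biased toward G and away from C to keep spurious CpGs and
    # C-rich stretches rare (post-conversion templates stay informative)
    seq = list(rng.choice(list("ACGT"), size=length, p=[0.28, 0.10, 0.30, 0.32]))
    regions = []
    snps: list[SnpVariant] = []
    shoulder = "GAGGTAGGTGAGGTTGAGGTAGGATGGTGAGGTAGGTTGAGGTGGATAGGTGAGGTTAGGTGAG"
    for k, center in enumerate((4_000, 10_000, 16_000)):
        core_start = center - 150
        # plant 8 CpGs in the core, spaced 30 bp
        for j in range(8):
            p = core_start + 30 * j
            seq[p] = "C"
            seq[p + 1] = "G"
        snp_pos = core_start + 15
        seq[snp_pos] = "A"
        snps.append(
            SnpVariant(f"rsT{k}", "chrT", snp_pos, "A", "G", het_freq=0.35)
        )
        # G-rich primer shoulders flanking the core
        left = core_start - len(shoulder) - 40
        for i, ch in enumerate(shoulder):
            seq[left + i] = ch
            seq[core_start + 260 + i] = ch
        region = GenomicInterval("chrT", left - 10, core_start + 260 + len(shoulder) + 10)
        # scrub background CpGs inside the region but outside the planted
        # core, so the amplicon payload is exactly the engineered one
        for i in range(region.start, region.end):
            if seq[i] == "C" and seq[i + 1] == "G" and not core_start <= i < core_start + 212:
                seq[i] = "A"
        regions.append(region)
    # common SNPs outside the cores that must be masked away from primers
    for k in range(10):
        pos = 1_000 + 1_800 * k + 73
        snps.append(SnpVariant(f"rsM{k}", "chrT", pos, "C", "T", het_freq=0.05))
    genome = {"chrT": "".join(seq)}
    cpgs = [i for i in range(length - 1) if genome["chrT"][i : i + 2] == "CG"]
    return genome, snps, {"chrT": cpgs}, regions


def primer_design_soundness(
    seed: int = 0, c: ad.DesignConstraints | None = None
) -> dict[str, float]:
    """Design a panel on the toy genome and audit every printed constraint
    on every emitted pair, plus determinism across a re-run.

    Returns the pair count, the total number of constraint violations
    (0 for a sound design) and a determinism flag.
    """
    c = c or ad.DesignConstraints()
    genome, snps, cpgs, regions = toy_design_genome(seed)
    panel = ad.design_panel(genome, snps, cpgs, regions, c)
    panel2 = ad.design_panel(genome, snps, cpgs, regions, c)
    templates = ad.convert_and_mask(genome, snps, c)
    violations = 0
    for pair in panel:
        for primer, tm, gc, n_cpg in (
            (pair.forward, pair.tm_forward, pair.gc_forward, pair.cpgs_forward),
            (pair.reverse, pair.tm_reverse, pair.gc_reverse, pair.cpgs_reverse),
        ):
            violations += not c.tm_range[0] <= tm <= c.tm_range[1]
            violations += not c.gc_range[0] <= gc <= c.gc_range[1]
            violations += n_cpg > c.max_cpgs_per_primer
            violations += "N" in primer
        violations += not c.amplicon_size[0] <= pair.size <= c.amplicon_size[1]
        ok, hits = ad.offtarget_scan(pair, templates, c)
        violations += not ok
        inner = [
            p
            for p in cpgs["chrT"]
            if pair.product.start + len(pair.forward) <= p < pair.product.end - len(pair.reverse)
        ]
        violations += len(inner) < c.min_amplicon_cpgs
    return {
        "n_pairs": len(panel),
        "n_violations": violations,
        "deterministic": float(panel == panel2),
    }
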