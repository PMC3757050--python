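"""Per-sample ASM testing, tissue-level heat-map aggregation and DMR calls.

A sample shows allele-specific methylation (ASM) when the per-read
methylated fractions of its two allele-specific clone sets differ by a
two-sample t-test.  Per amplicon and tissue, sample results are collapsed
to one heat-map cell using the averaging and category rules of the source
heat maps; runs of ASM-positive amplicons then delimit differentially
methylated regions (DMRs) at amplicon resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from statistics import fmean

from scipy import stats

from .allele_methylation import (
    AlleleProfile,
    BisRead,
    GenotypeCall,
    allele_profile,
    call_sample_genotype,
    read_meth_fraction,
    split_reads_by_allele,
)
from .core_model import GenomicInterval, SnpVariant, Thresholds

__all__ = [
    "AsmResult",
    "TissueCell",
    "AsmCallMatrix",
    "DmrCall",
    "asm_test_sample",
    "aggregate_tissue",
    "delineate_dmr",
    "annotate_dmr",
    "build_call_matrix",
]

#: heat-map cell categories
RED_CATEGORIES = frozenset({"solid_red", "stippled_red"})
CATEGORIES = RED_CATEGORIES | {"hom_all", "het_no_asm", "stippled_grey"}


@dataclass(frozen=True)
class AsmResult:
    """Per-sample allele-contrast: Δ methylation, t-test p, significance.

    ``delta`` is signed (allele A minus allele B mean per-read fraction);
    ``significant`` additionally requires at least
    ``asm_min_reads_per_allele`` reads on each allele.
    """

    sample_id: str
    delta: float
    p_value: float
    n_a: int
    n_b: int
    hyper_allele: str | None
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class TissueCell:
    """One amplicon × tissue cell of the ASM heat map."""

    amplicon_id: str
    tissue: str
    n_het: int
    mean_abs_delta: float | None
    frac_significant: float | None
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown heat-map category {self.category!r}")


@dataclass
class AsmCallMatrix:
    """ASM heat map: ordered amplicons × tissues grid of TissueCells."""

    amplicons: list[tuple[str, GenomicInterval]]
    tissues: list[str]
    cells: dict[tuple[str, str], TissueCell]

    def __post_init__(self) -> None:
        starts = [(iv.chrom, iv.start) for _, iv in self.amplicons]
        if starts != sorted(starts):
            raise ValueError("amplicons must be ordered by genomic start")

    def cell(self, amplicon_id: str, tissue: str) -> TissueCell:
        return self.cells[(amplicon_id, tissue)]


@dataclass(frozen=True)
class DmrCall:
    """A differentially methylated region delimited at amplicon resolution."""

    interval: GenomicInterval
    amplicon_ids: tuple[str, ...]
    tissues: tuple[str, ...]
    ctcf_overlap: bool | None = None
    cgi_overlap: bool | None = None


def asm_test_sample(
    reads_a: list[BisRead],
    reads_b: list[BisRead],
    th: Thresholds,
    sample_id: str = "",
    alleles: tuple[str, str] = ("A", "B"),
    exclude_positions: frozenset[int] | set[int] = frozenset(),
) -> AsmResult:
    """Welch two-sided t-test between the per-read methylated fractions of
    the two allele clone sets of one heterozygous sample.

    Δ and the hypermethylated allele are always reported; ``significant``
    requires p < ``asm_alpha`` and ≥ ``asm_min_reads_per_allele`` reads on
    both alleles.  When both clone sets have zero variance the t statistic
    is undefined: equal means give p = 1, separated means give p = 0
    (flagged degenerate).
    """
    fa = [
        f for r in reads_a if (f := read_meth_fraction(r, exclude_positions)) is not None
    ]
    fb = [
        f for r in reads_b if (f := read_meth_fraction(r, exclude_positions)) is not None
    ]
    if not fa or not fb:
        raise ValueError("both alleles must contribute at least one informative read")
    mean_a, mean_b = fmean(fa), fmean(fb)
    delta = mean_a - mean_b
    degenerate = False
    var_a = sum((x - mean_a) ** 2 for x in fa)
    var_b = sum((x - mean_b) ** 2 for x in fb)
    if (var_a == 0.0 and var_b == 0.0) or len(fa) < 2 or len(fb) < 2:
        degenerate = True
        p = 1.0 if math.isclose(mean_a, mean_b, abs_tol=1e-12) else 0.0
    else:
        p = float(stats.ttest_ind(fa, fb, equal_var=False).pvalue)
        if math.isnan(p):  # zero variance in one group, scipy returns nan
            degenerate = True
            p = 1.0 if math.isclose(mean_a, mean_b, abs_tol=1e-12) else 0.0
    if delta > 0:
        hyper = alleles[0]
    elif delta < 0:
        hyper = alleles[1]
    else:
        hyper = None
    significant = (
        p < th.asm_alpha
        and len(reads_a) >= th.asm_min_reads_per_allele
        and len(reads_b) >= th.asm_min_reads_per_allele
    )
    return AsmResult(
        sample_id=sample_id,
        delta=delta,
        p_value=p,
        n_a=len(reads_a),
        n_b=len(reads_b),
        hyper_allele=hyper,
        significant=significant,
        degenerate=degenerate,
    )


def aggregate_tissue(
    amplicon_id: str,
    tissue: str,
    results: list[AsmResult],
    genotypes: list[GenotypeCall],
    th: Thresholds,
) -> TissueCell:
    """Collapse the per-sample results of one amplicon × tissue to a cell.

    Category rules: ``hom_all`` when no sample is heterozygous;
    ``stippled_grey`` when no sample reaches read depth 10; ``solid_red``
    when the mean |Δ| over het samples is ≥ 0.30 with ≥2 het samples and at
    least half of them individually significant; ``stippled_red`` when the
    mean |Δ| exceeds 0.30 but rests on a single het sample or on fewer than
    half significant; otherwise ``het_no_asm``.
    """
    n_het = sum(1 for g in genotypes if g.status == "het")
    if n_het == 0:
        return TissueCell(amplicon_id, tissue, 0, None, None, "hom_all")
    if all(g.n_reads < th.genotype_min_reads for g in genotypes):
        return TissueCell(amplicon_id, tissue, n_het, None, None, "stippled_grey")
    if not results:
        return TissueCell(amplicon_id, tissue, n_het, None, None, "het_no_asm")
    mean_abs_delta = fmean(abs(r.delta) for r in results)
    frac_sig = sum(r.significant for r in results) / len(results)
    if mean_abs_delta >= th.asm_delta_min and n_het >= 2 and frac_sig >= 0.5:
        category = "solid_red"
    elif mean_abs_delta > th.asm_delta_min and (n_het == 1 or frac_sig < 0.5):
        category = "stippled_red"
    else:
        category = "het_no_asm"
    return TissueCell(amplicon_id, tissue, n_het, mean_abs_delta, frac_sig, category)


def delineate_dmr(matrix: AsmCallMatrix) -> list[DmrCall]:
    """Delimit DMRs as maximal runs of ASM-positive amplicons.

    Per tissue, contiguous runs of amplicons whose cell is solid or
    stippled red are collected; runs from different tissues are merged when
    they share at least one amplicon.  Each DMR's interval spans from the
    first to the last member amplicon.
    """
    if not matrix.amplicons:
        return []
    runs: list[tuple[int, int, str]] = []  # (first_idx, last_idx, tissue)
    for tissue in matrix.tissues:
        start = None
        for i, (amp_id, _) in enumerate(matrix.amplicons):
            cell = matrix.cells.get((amp_id, tissue))
            red = cell is not None and cell.category in RED_CATEGORIES
            if red and start is None:
                start = i
            elif not red and start is not None:
                runs.append((start, i - 1, tissue))
                start = None
        if start is not None:
            runs.append((start, len(matrix.amplicons) - 1, tissue))
    # merge runs sharing >=1 amplicon index
    merged: list[tuple[int, int, set[str]]] = []
    for lo, hi, tissue in sorted(runs):
        for k, (mlo, mhi, tset) in enumerate(merged):
            if lo <= mhi and mlo <= hi:
                merged[k] = (min(lo, mlo), max(hi, mhi), tset | {tissue})
                break
        else:
            merged.append((lo, hi, {tissue}))
    # a second pass in case a late merge bridged two earlier groups
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                ilo, ihi, iset = merged[i]
                jlo, jhi, jset = merged[j]
                if ilo <= jhi and jlo <= ihi:
                    merged[i] = (min(ilo, jlo), max(ihi, jhi), iset | jset)
                    del merged[j]
                    changed = True
                    break
            if changed:
                break
    dmrs = []
    for lo, hi, tissues in sorted(merged):
        members = matrix.amplicons[lo : hi + 1]
        chrom = members[0][1].chrom
        interval = GenomicInterval(
            chrom, min(iv.start for _, iv in members), max(iv.end for _, iv in members)
        )
        dmrs.append(
            DmrCall(
                interval=interval,
                amplicon_ids=tuple(a for a, _ in members),
                tissues=tuple(sorted(tissues)),
            )
        )
    return dmrs


def annotate_dmr(
    dmr: DmrCall,
    ctcf_peaks: list[GenomicInterval],
    cgi_track: list[GenomicInterval],
) -> DmrCall:
    """Flag a DMR for overlap with CTCF peaks and CpG islands."""
    return replace(
        dmr,
        ctcf_overlap=any(dmr.interval.overlaps(p) for p in ctcf_peaks),
        cgi_overlap=any(dmr.interval.overlaps(c) for c in cgi_track),
    )


def build_call_matrix(
    reads_by_sample: dict[tuple[str, str, str], list[BisRead]],
    amplicons: list[tuple[str, GenomicInterval, SnpVariant]],
    th: Thresholds,
    exclude_positions: frozenset[int] | set[int] = frozenset(),
) -> AsmCallMatrix:
    """Run the full per-sample pipeline and assemble the ASM heat map.

    ``reads_by_sample`` keys are (amplicon_id, tissue, sample_id).
    """
    ordered = sorted(amplicons, key=lambda a: (a[1].chrom, a[1].start))
    tissues = sorted({k[1] for k in reads_by_sample})
    cells: dict[tuple[str, str], TissueCell] = {}
    for amp_id, _, snp in ordered:
        for tissue in tissues:
            genotypes: list[GenotypeCall] = []
            results: list[AsmResult] = []
            for (a, t, sample_id), reads in reads_by_sample.items():
                if a != amp_id or t != tissue:
                    continue
                gt = call_sample_genotype(reads, snp, th)
                genotypes.append(gt)
                if gt.status != "het":
                    continue
                ra, rb, _ = split_reads_by_allele(reads, snp)
                if not ra or not rb:
                    continue
                results.append(
                    asm_test_sample(
                        ra,
                        rb,
                        th,
                        sample_id=sample_id,
                        alleles=snp.alleles,
                        exclude_positions=exclude_positions,
                    )
                )
            cells[(amp_id, tissue)] = aggregate_tissue(
                amp_id, tissue, results, genotypes, th
            )
    return AsmCallMatrix(
        amplicons=[(a, iv) for a, iv, _ in ordered], tissues=tissues, cells=cells
    )
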