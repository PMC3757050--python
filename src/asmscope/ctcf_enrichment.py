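"""Genome-scale CpG methylation classes, CTCF co-localization and GWAS
cross-tabulation.

Every CpG with whole-genome bisulfite coverage is placed in one of four
methylation classes — ASM (externally flagged), fully methylated (>90% of
reads methylated), partially methylated (10–90%) or unmethylated (<10%) —
and annotated with its genomic context (intergenic, intragenic, promoter
= ±1 kb of a TSS, CGI = within 250 bp of a CpG island, promoter-CGI =
both) and with CTCF proximity (any peak intersecting a 500 bp window
centred on the CpG).  Enrichment of ASM CpGs near CTCF is tested per
context stratum with one-sided Fisher exact tests against each non-ASM
class.  CTCF peaks with ≥2 ASM CpGs in a 1 kb peak-centred window are
enumerated and cross-tabulated to nearby genes (≤100 kb), GWAS SNPs
(p ≤ 1e-6) and haplotype blocks.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace

import pandas as pd
from scipy import stats

from .core_model import CpgSite, GenomicInterval, Thresholds, window_around
from .io_formats import GeneRecord, GwasSnp

__all__ = [
    "CpgClassRecord",
    "AsmCtcfSite",
    "EnrichmentResult",
    "STRATA",
    "classify_cpg",
    "annotate_context",
    "flag_ctcf_near",
    "build_cpg_records",
    "enrichment_tables",
    "find_asm_ctcf_sites",
    "crosstab_gwas",
]

logger = logging.getLogger(__name__)

METH_CLASSES = ("asm", "full", "partial", "unmeth")
STRATA = ("intergenic", "intragenic", "promoter", "cgi", "promoter_cgi")


@dataclass(frozen=True)
class CpgClassRecord:
    """One genome-scale CpG with class, context labels and CTCF flag."""

    site: CpgSite
    n_meth_reads: int
    n_total_reads: int
    asm_flag: bool
    meth_class: str
    context: frozenset[str]
    ctcf_near: bool

    def __post_init__(self) -> None:
        if self.meth_class not in METH_CLASSES:
            raise ValueError(f"unknown methylation class {self.meth_class!r}")
        if (self.meth_class == "asm") != self.asm_flag:
            raise ValueError("meth_class 'asm' must mirror asm_flag")
        if "promoter_cgi" in self.context and not (
            {"promoter", "cgi"} <= self.context
        ):
            raise ValueError("promoter_cgi context requires promoter and cgi")


@dataclass(frozen=True)
class AsmCtcfSite:
    """A CTCF peak with ≥2 ASM CpGs in its 1 kb centred window."""

    peak: GenomicInterval
    n_asm_cpgs_1kb: int
    asm_cpg_positions: tuple[int, ...]
    nearest_gene: str | None = None
    gene_distance: int | None = None
    gwas_hits: tuple[tuple[str, str, float], ...] = ()
    same_block: bool | None = None


@dataclass(frozen=True)
class EnrichmentResult:
    """One stratum × comparison 2×2 Fisher test.

    ``table`` rows are (ASM, comparison class); columns (near CTCF, not).
    The odds ratio uses a Haldane 0.5 correction for display only — the
    p-value is always computed on the raw counts.
    """

    stratum: str
    comparison: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    fisher_p: float
    degenerate: bool = False


def classify_cpg(n_meth: int, n_total: int, asm_flag: bool = False) -> str:
    """Methylation class of one CpG from its read counts.

    ASM when externally flagged; otherwise fully methylated iff the
    methylated fraction strictly exceeds 0.90, unmethylated iff strictly
    below 0.10, else partial (a fraction of exactly 0.90 or 0.10 is
    partial).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive; unclassifiable CpG")
    if not 0 <= n_meth <= n_total:
        raise ValueError("n_meth must lie in [0, n_total]")
    if asm_flag:
        return "asm"
    f = n_meth / n_total
    if f > 0.90:
        return "full"
    if f < 0.10:
        return "unmeth"
    return "partial"


def annotate_context(
    site: CpgSite,
    genes: list[GeneRecord],
    cgi_track: list[GenomicInterval],
    th: Thresholds,
) -> frozenset[str]:
    """Genomic context labels of one CpG.

    promoter: within ``promoter_flank_bp`` of any TSS; cgi: within
    ``cgi_proximity_bp`` of a CGI; promoter_cgi: both; intragenic: inside
    a gene body and not promoter; intergenic otherwise.
    """
    promoter = any(
        g.interval.chrom == site.chrom and abs(site.pos - g.tss) <= th.promoter_flank_bp
        for g in genes
    )
    cgi = any(
        c.chrom == site.chrom
        and c.start - th.cgi_proximity_bp <= site.pos < c.end + th.cgi_proximity_bp
        for c in cgi_track
    )
    in_body = any(g.interval.contains(site.chrom, site.pos) for g in genes)
    labels = set()
    if promoter:
        labels.add("promoter")
    if cgi:
        labels.add("cgi")
    if promoter and cgi:
        labels.add("promoter_cgi")
    if in_body and not promoter:
        labels.add("intragenic")
    if not in_body and not promoter:
        labels.add("intergenic")
    return frozenset(labels)


def flag_ctcf_near(
    site: CpgSite, peaks: list[GenomicInterval], th: Thresholds
) -> bool:
    """True iff any CTCF peak intersects the ``ctcf_window_bp`` window
    centred on the CpG.  ``peaks`` should be the union of all supplied
    peak sets (a site present in at least one dataset counts)."""
    window = window_around(site.chrom, site.pos, th.ctcf_window_bp)
    return any(window.overlaps(p) for p in peaks)


class _IntervalIndex:
    """Per-chromosome sorted-interval index for point/window queries."""

    def __init__(self, intervals: list[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        self.max_len = max((iv.length for iv in intervals), default=0)
        for iv in sorted(intervals):
            starts, ends = self._by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        lo = bisect_left(starts, start - self.max_len)
        hi = bisect_left(starts, end)
        return any(ends[i] > start for i in range(lo, hi))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.any_overlap(chrom, pos, pos + 1)


def build_cpg_records(
    counts: pd.DataFrame,
    peaks: list[GenomicInterval],
    genes: list[GeneRecord],
    cgi_track: list[GenomicInterval],
    th: Thresholds,
    exclude_polymorphic: bool = True,
) -> list[CpgClassRecord]:
    """Classify and annotate a per-CpG read-count table.

    Expected columns: chrom, pos, n_meth, n_total, asm_flag and optional
    is_polymorphic.  CpGs with zero coverage are excluded with a log
    message; polymorphic CpGs are excluded by default (toggleable), since
    CpG-destroying SNPs mimic ASM.  Feature lookups run on sorted
    interval indexes, so genome-scale tables annotate in O(n log n).
    """
    peak_index = _IntervalIndex(peaks)
    body_index = _IntervalIndex([g.interval for g in genes])
    cgi_index = _IntervalIndex(
        [
            GenomicInterval(
                c.chrom, max(0, c.start - th.cgi_proximity_bp), c.end + th.cgi_proximity_bp
            )
            for c in cgi_track
        ]
    )
    tss_index = _IntervalIndex(
        [
            GenomicInterval(
                g.interval.chrom,
                max(0, g.tss - th.promoter_flank_bp),
                g.tss + th.promoter_flank_bp + 1,
            )
            for g in genes
        ]
    )
    half = th.ctcf_window_bp // 2

    records: list[CpgClassRecord] = []
    n_skipped = 0
    has_poly = "is_polymorphic" in counts.columns
    for row in counts.itertuples():
        if row.n_total == 0:
            n_skipped += 1
            continue
        poly = bool(row.is_polymorphic) if has_poly else False
        if exclude_polymorphic and poly:
            n_skipped += 1
            continue
        chrom, pos = row.chrom, int(row.pos)
        promoter = tss_index.contains_point(chrom, pos)
        cgi = cgi_index.contains_point(chrom, pos)
        in_body = body_index.contains_point(chrom, pos)
        labels = set()
        if promoter:
            labels.add("promoter")
        if cgi:
            labels.add("cgi")
        if promoter and cgi:
            labels.add("promoter_cgi")
        if in_body and not promoter:
            labels.add("intragenic")
        if not in_body and not promoter:
            labels.add("intergenic")
        site = CpgSite(chrom, pos, is_polymorphic=poly)
        records.append(
            CpgClassRecord(
                site=site,
                n_meth_reads=int(row.n_meth),
                n_total_reads=int(row.n_total),
                asm_flag=bool(row.asm_flag),
                meth_class=classify_cpg(int(row.n_meth), int(row.n_total), bool(row.asm_flag)),
                context=frozenset(labels),
                ctcf_near=peak_index.any_overlap(
                    chrom, max(0, pos - half), pos + (th.ctcf_window_bp - half)
                ),
            )
        )
    if n_skipped:
        logger.info("%d CpG(s) excluded (zero coverage or polymorphic)", n_skipped)
    return records


def enrichment_tables(
    records: list[CpgClassRecord],
    strata: tuple[str, ...] = STRATA,
    comparisons: tuple[str, ...] = ("full", "partial", "unmeth"),
) -> list[EnrichmentResult]:
    """Context-stratified one-sided Fisher tests of ASM-CTCF association.

    Per stratum and per comparison class, the 2×2 table counts (class ∈
    {asm, comparison}) × (CTCF near or not) and is tested one-sided in
    the enrichment direction (ASM more often near CTCF).  An empty margin
    yields p = 1 with a degenerate flag.
    """
    results = []
    for stratum in strata:
        in_stratum = [r for r in records if stratum in r.context]
        asm = [r for r in in_stratum if r.meth_class == "asm"]
        a_near = sum(r.ctcf_near for r in asm)
        a_far = len(asm) - a_near
        for comparison in comparisons:
            other = [r for r in in_stratum if r.meth_class == comparison]
            o_near = sum(r.ctcf_near for r in other)
            o_far = len(other) - o_near
            table = ((a_near, a_far), (o_near, o_far))
            degenerate = (
                min(a_near + a_far, o_near + o_far) == 0
                or a_near + o_near == 0
                or a_far + o_far == 0
            )
            if degenerate:
                p = 1.0
            else:
                p = float(stats.fisher_exact(table, alternative="greater")[1])
            num = (a_near + 0.5) * (o_far + 0.5)
            den = (a_far + 0.5) * (o_near + 0.5)
            results.append(
                EnrichmentResult(
                    stratum=stratum,
                    comparison=comparison,
                    table=table,
                    odds_ratio=num / den,
                    fisher_p=p,
                    degenerate=degenerate,
                )
            )
    return results


def _peak_center(peak: GenomicInterval, summit: int | None = None) -> int:
    return summit if summit is not None else peak.midpoint


def find_asm_ctcf_sites(
    peaks: list[GenomicInterval],
    asm_records: list[CpgClassRecord],
    th: Thresholds,
    summits: dict[GenomicInterval, int] | None = None,
) -> list[AsmCtcfSite]:
    """Enumerate CTCF peaks with ≥ ``asm_cpgs_per_site_min`` ASM CpGs in a
    1 kb window centred on the peak (midpoint, or summit when supplied).

    The window is half-open: an ASM CpG exactly at the right edge does
    not count.
    """
    asm_by_chrom: dict[str, list[int]] = {}
    for r in asm_records:
        if r.meth_class != "asm":
            raise ValueError("asm_records must be restricted to meth_class='asm'")
        asm_by_chrom.setdefault(r.site.chrom, []).append(r.site.pos)
    for positions in asm_by_chrom.values():
        positions.sort()
    sites = []
    for peak in peaks:
        center = _peak_center(peak, summits.get(peak) if summits else None)
        window = window_around(peak.chrom, center, th.asm_ctcf_window_bp)
        positions = asm_by_chrom.get(peak.chrom, [])
        lo = bisect_left(positions, window.start)
        hi = bisect_left(positions, window.end)
        if hi - lo >= th.asm_cpgs_per_site_min:
            sites.append(
                AsmCtcfSite(
                    peak=peak,
                    n_asm_cpgs_1kb=hi - lo,
                    asm_cpg_positions=tuple(positions[lo:hi]),
                )
            )
    return sites


def crosstab_gwas(
    sites: list[AsmCtcfSite],
    genes: list[GeneRecord],
    gwas_snps: list[GwasSnp],
    blocks: list[GenomicInterval] | None,
    th: Thresholds,
) -> list[AsmCtcfSite]:
    """Annotate ASM-CTCF sites with nearby genes, GWAS SNPs and haplotype
    blocks.

    The nearest gene within ``gene_distance_bp`` of the peak is attached.
    ``same_block`` is true iff a single haplotype block contains the peak,
    at least one of the site's ASM CpGs, and at least one GWAS SNP (which
    must be pre-filtered to p ≤ ``gwas_p_max``); with no blocks supplied
    it is left unknown (None).
    """
    out = []
    for site in sites:
        best: tuple[int, str] | None = None
        for g in genes:
            d = site.peak.distance_to(g.interval)
            if d is None or d > th.gene_distance_bp:
                continue
            if best is None or d < best[0]:
                best = (d, g.name)
        hits = []
        same_block: bool | None = None
        if blocks is not None:
            same_block = False
            for block in blocks:
                if not block.overlaps(site.peak):
                    continue
                if not any(
                    block.contains(site.peak.chrom, p) for p in site.asm_cpg_positions
                ):
                    continue
                snps_in = [
                    s
                    for s in gwas_snps
                    if s.p <= th.gwas_p_max and block.contains(s.chrom, s.pos)
                ]
                if snps_in:
                    same_block = True
                    hits.extend((s.snp, s.trait, s.p) for s in snps_in)
        out.append(
            replace(
                site,
                nearest_gene=best[1] if best else None,
                gene_distance=best[0] if best else None,
                gwas_hits=tuple(hits),
                same_block=same_block,
            )
        )
    return out
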