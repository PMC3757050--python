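import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmscope.calibration import fisher_one_sided_oracle
from asmscope.core_model import CpgSite, GenomicInterval, Thresholds
from asmscope.ctcf_enrichment import (
    AsmCtcfSite,
    CpgClassRecord,
    annotate_context,
    classify_cpg,
    crosstab_gwas,
    enrichment_tables,
    find_asm_ctcf_sites,
    flag_ctcf_near,
)
from asmscope.io_formats import GeneRecord, GwasSnp


class TestClassifyCpg:
    @pytest.mark.parametrize(
        "n_meth,n_total,expected",
        [
            (95, 100, "full"),
            (50, 100, "partial"),
            (9, 100, "unmeth"),
            (90, 100, "partial"),  # exactly 90% is not "full"
            (10, 100, "partial"),  # exactly 10% is not "unmeth"
            (91, 100, "full"),
        ],
    )
    def test_boundaries(self, n_meth, n_total, expected):
        assert classify_cpg(n_meth, n_total) == expected

    def test_asm_flag_overrides(self):
        assert classify_cpg(95, 100, asm_flag=True) == "asm"

    def test_zero_coverage_error(self):
        with pytest.raises(ValueError):
            classify_cpg(0, 0)


class TestContext:
    def _gene(self, start, end, tss, name="G1"):
        return GeneRecord(name, GenomicInterval("chr1", start, end), "+", tss)

    def test_promoter_within_1kb_downstream_of_tss(self, th):
        site = CpgSite("chr1", 10_300)
        ctx = annotate_context(site, [self._gene(10_000, 15_000, 10_000)], [], th)
        assert "promoter" in ctx and "intragenic" not in ctx

    def test_cgi_proximal_intergenic(self, th):
        site = CpgSite("chr1", 5_000)
        cgi = [GenomicInterval("chr1", 5_200, 5_600)]
        ctx = annotate_context(site, [self._gene(50_000, 60_000, 50_000)], cgi, th)
        assert ctx == frozenset({"cgi", "intergenic"})

    def test_intragenic_far_from_tss(self, th):
        site = CpgSite("chr1", 20_000)
        ctx = annotate_context(site, [self._gene(10_000, 30_000, 10_000)], [], th)
        assert ctx == frozenset({"intragenic"})

    def test_promoter_cgi_requires_both(self, th):
        site = CpgSite("chr1", 10_300)
        ctx = annotate_context(
            site,
            [self._gene(10_000, 15_000, 10_000)],
            [GenomicInterval("chr1", 10_250, 10_400)],
            th,
        )
        assert {"promoter", "cgi", "promoter_cgi"} <= ctx


class TestCtcfFlag:
    def test_peak_100bp_away(self, th):
        assert flag_ctcf_near(CpgSite("chr1", 1000), [GenomicInterval("chr1", 1100, 1150)], th)

    def test_peak_outside_window(self, th):
        assert not flag_ctcf_near(CpgSite("chr1", 1000), [GenomicInterval("chr1", 1400, 1450)], th)

    def test_empty_track(self, th):
        assert not flag_ctcf_near(CpgSite("chr1", 1000), [], th)


def _record(pos, meth_class, context, near):
    n_meth = {"asm": 15, "full": 29, "partial": 15, "unmeth": 0}[meth_class]
    return CpgClassRecord(
        site=CpgSite("chr1", pos),
        n_meth_reads=n_meth,
        n_total_reads=30,
        asm_flag=meth_class == "asm",
        meth_class=meth_class,
        context=frozenset([context] if context != "promoter_cgi" else ["promoter", "cgi", "promoter_cgi"]),
        ctcf_near=near,
    )


class TestEnrichment:
    def test_table_p_equals_oracle(self):
        records = []
        pos = 0
        for cls, near, count in [("asm", True, 8), ("asm", False, 2), ("full", True, 20), ("full", False, 70)]:
            for _ in range(count):
                records.append(_record(pos, cls, "promoter", near))
                pos += 1000
        (res,) = enrichment_tables(records, strata=("promoter",), comparisons=("full",))
        assert res.table == ((8, 2), (20, 70))
        assert res.fisher_p == pytest.approx(fisher_one_sided_oracle(8, 2, 20, 70), abs=1e-12)

    def test_all_near_degenerate(self):
        records = [_record(i * 1000, c, "cgi", True) for i, c in enumerate(["asm"] * 5 + ["full"] * 5)]
        (res,) = enrichment_tables(records, strata=("cgi",), comparisons=("full",))
        assert res.degenerate and res.fisher_p == 1.0

    def test_class_counts_partition(self):
        from asmscope.simdata import simulate_wgbs_table
        from asmscope.ctcf_enrichment import build_cpg_records

        counts, peaks, genes, cgis, _ = simulate_wgbs_table(500, seed=3)
        records = build_cpg_records(counts, peaks, genes, cgis, Thresholds())
        by_class = {c: sum(r.meth_class == c for r in records) for c in ("asm", "full", "partial", "unmeth")}
        assert sum(by_class.values()) == len(records) == 500


@settings(max_examples=300, derandomize=True)
@given(
    a=st.integers(0, 40),
    b=st.integers(0, 40),
    c=st.integers(0, 40),
    d=st.integers(0, 40),
)
def test_fisher_implementation_matches_exact_tail_oracle(a, b, c, d):
    from scipy import stats

    if min(a + b, c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return
    impl = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
    assert impl == pytest.approx(fisher_one_sided_oracle(a, b, c, d), abs=1e-10)


class TestAsmCtcfSites:
    def _asm_records(self, positions):
        return [_record(p, "asm", "intergenic", False) for p in positions]

    def test_two_cpgs_in_window_qualifies(self, th):
        peak = GenomicInterval("chr1", 9_950, 10_050)  # midpoint 10_000
        sites = find_asm_ctcf_sites([peak], self._asm_records([9_700, 10_300]), th)
        assert len(sites) == 1 and sites[0].n_asm_cpgs_1kb == 2

    def test_single_cpg_excluded(self, th):
        peak = GenomicInterval("chr1", 9_950, 10_050)
        assert find_asm_ctcf_sites([peak], self._asm_records([10_300]), th) == []

    def test_window_edge_half_open(self, th):
        peak = GenomicInterval("chr1", 9_950, 10_050)
        # window is [9500, 10500): a CpG exactly at 10_500 does not count
        sites = find_asm_ctcf_sites([peak], self._asm_records([9_500, 10_500]), th)
        assert len(sites) == 0
        sites = find_asm_ctcf_sites([peak], self._asm_records([9_500, 10_499]), th)
        assert len(sites) == 1

    def test_non_asm_record_rejected(self, th):
        peak = GenomicInterval("chr1", 0, 100)
        with pytest.raises(ValueError):
            find_asm_ctcf_sites([peak], [_record(50, "full", "cgi", True)], th)


class TestGwasCrosstab:
    def _site(self):
        return AsmCtcfSite(
            peak=GenomicInterval("chr1", 9_950, 10_050),
            n_asm_cpgs_1kb=2,
            asm_cpg_positions=(9_700, 10_300),
        )

    def test_same_block(self, th):
        blocks = [GenomicInterval("chr1", 9_000, 11_000)]
        gwas = [GwasSnp("rsG", "chr1", 10_800, "asthma", 1e-8)]
        (out,) = crosstab_gwas([self._site()], [], gwas, blocks, th)
        assert out.same_block is True
        assert out.gwas_hits == (("rsG", "asthma", 1e-8),)

    def test_gene_distance_cutoff(self, th):
        near = GeneRecord("NEAR", GenomicInterval("chr1", 109_000, 120_000), "+", 109_000)
        far = GeneRecord("FAR", GenomicInterval("chr1", 111_100, 130_000), "+", 111_100)
        (out,) = crosstab_gwas([self._site()], [near], [], None, th)
        assert out.nearest_gene == "NEAR" and out.gene_distance == 98_950
        (out,) = crosstab_gwas([self._site()], [far], [], None, th)
        assert out.nearest_gene is None

    def test_no_blocks_unknown(self, th):
        (out,) = crosstab_gwas([self._site()], [], [], None, th)
        assert out.same_block is None

    def test_block_without_gwas_snp(self, th):
        blocks = [GenomicInterval("chr1", 9_000, 11_000)]
        (out,) = crosstab_gwas([self._site()], [], [], blocks, th)
        assert out.same_block is False


def test_planted_enrichment_detected_in_planted_stratum_only_small():
    """Reduced-replicate version of the planted odds-ratio recovery
    (full 20-run sweep in the acceptance suite)."""
    from asmscope.calibration import planted_enrichment_recovery

    out = planted_enrichment_recovery(n_runs=3, seed=5)
    assert out["detected_exclusively_rate"] == 1.0
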