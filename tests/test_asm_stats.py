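import numpy as np
import pytest
from scipy import stats

from asmscope.asm_stats import (
    AsmCallMatrix,
    AsmResult,
    TissueCell,
    aggregate_tissue,
    annotate_dmr,
    asm_test_sample,
    delineate_dmr,
)
from asmscope.allele_methylation import GenotypeCall
from asmscope.core_model import GenomicInterval
from tests.conftest import make_read


def _result(delta, significant, sample="s", p=0.01):
    return AsmResult(sample, delta, p, 20, 20, "A" if delta > 0 else "G", significant)


def _gt(status="het", n=30):
    return GenotypeCall(status, n, 0.4 if status == "het" else 0.05)


class TestAsmTest:
    def test_maximal_separation(self, th):
        ra = [make_read("A", "UUUU") for _ in range(5)]
        rb = [make_read("G", "MMMM") for _ in range(5)]
        res = asm_test_sample(ra, rb, th, alleles=("A", "G"))
        assert abs(res.delta) == 1.0
        assert res.significant and res.degenerate and res.p_value == 0.0
        assert res.hyper_allele == "G"

    def test_four_reads_never_significant(self, th):
        ra = [make_read("A", "UUUU") for _ in range(4)]
        rb = [make_read("G", "MMMM") for _ in range(9)]
        res = asm_test_sample(ra, rb, th, alleles=("A", "G"))
        assert res.p_value == 0.0 and not res.significant

    def test_zero_variance_equal_means_p_one(self, th):
        ra = [make_read("A", "MMUU") for _ in range(6)]
        rb = [make_read("G", "MMUU") for _ in range(6)]
        res = asm_test_sample(ra, rb, th, alleles=("A", "G"))
        assert res.p_value == 1.0 and res.degenerate and not res.significant

    @pytest.mark.parametrize("seed", [0, 3, 5, 7])
    def test_welch_p_close_to_permutation_oracle(self, th, seed):
        """In the decision-relevant regime the t-test p tracks the exact
        permutation null of the per-read fractions."""
        rng = np.random.default_rng(seed)
        ka = rng.binomial(16, 0.45, size=12)
        kb = rng.binomial(16, 0.6, size=12)
        ra = [make_read("A", "M" * k + "U" * (16 - k)) for k in ka]
        rb = [make_read("G", "M" * k + "U" * (16 - k)) for k in kb]
        res = asm_test_sample(ra, rb, th, alleles=("A", "G"))
        pool = np.concatenate([ka, kb]) / 16
        obs = abs(pool[:12].mean() - pool[12:].mean())
        idx = np.array([rng.permutation(24) for _ in range(10_000)])
        perms = pool[idx]
        diffs = np.abs(perms[:, :12].mean(axis=1) - perms[:, 12:].mean(axis=1))
        perm_p = float((diffs >= obs - 1e-12).mean())
        assert res.p_value == pytest.approx(perm_p, abs=0.02)


class TestAggregation:
    def test_single_het_sample_with_strong_delta_is_stippled(self, th):
        cell = aggregate_tissue("a", "PBL", [_result(0.45, True)], [_gt()], th)
        assert cell.category == "stippled_red"

    def test_multiple_concordant_hets_solid(self, th):
        results = [_result(0.6, True), _result(-0.62, True), _result(0.58, True), _result(0.6, False, p=0.2)]
        cell = aggregate_tissue("a", "PBL", results, [_gt()] * 4, th)
        assert cell.category == "solid_red"
        assert cell.mean_abs_delta == pytest.approx(0.6, abs=0.01)

    def test_exactly_half_significant_is_solid(self, th):
        results = [_result(0.5, True), _result(0.5, False, p=0.3)]
        cell = aggregate_tissue("a", "PBL", results, [_gt()] * 2, th)
        assert cell.category == "solid_red"

    def test_minority_significant_is_stippled(self, th):
        results = [_result(0.5, True), _result(0.5, False, p=0.3), _result(0.5, False, p=0.3)]
        assert aggregate_tissue("a", "PBL", results, [_gt()] * 3, th).category == "stippled_red"

    def test_all_homozygous(self, th):
        cell = aggregate_tissue("a", "PBL", [], [_gt("hom_a"), _gt("hom_b")], th)
        assert cell.category == "hom_all"

    def test_insufficient_depth_stippled_grey(self, th):
        cell = aggregate_tissue("a", "PBL", [], [_gt("het", n=8), _gt("hom_a", n=6)], th)
        assert cell.category == "stippled_grey"

    def test_weak_delta_is_het_no_asm(self, th):
        results = [_result(0.1, False, p=0.6), _result(-0.05, False, p=0.8)]
        assert aggregate_tissue("a", "PBL", results, [_gt()] * 2, th).category == "het_no_asm"


def _matrix(categories, tissues=("PBL",), starts=None):
    amps = []
    cells = {}
    for i, _ in enumerate(categories):
        start = starts[i] if starts else 1000 * (i + 1)
        end = starts[i] + 300 if starts else 1000 * (i + 1) + 300
        amps.append((f"a{i}", GenomicInterval("chr1", start, end)))
    for t in tissues:
        for i, cat in enumerate(categories):
            cells[(f"a{i}", t)] = TissueCell(
                f"a{i}", t, 2, 0.5 if "red" in cat else None, 0.8 if "red" in cat else None, cat
            )
    return AsmCallMatrix(amps, list(tissues), cells)


class TestDmr:
    def test_single_run_detected(self):
        m = _matrix(["het_no_asm", "het_no_asm", "solid_red", "solid_red", "het_no_asm"])
        dmrs = delineate_dmr(m)
        assert len(dmrs) == 1
        assert dmrs[0].amplicon_ids == ("a2", "a3")
        assert dmrs[0].interval == GenomicInterval("chr1", 3000, 4300)

    def test_no_red_cells(self):
        assert delineate_dmr(_matrix(["het_no_asm", "hom_all", "stippled_grey"])) == []

    def test_elk3_panel_span(self):
        """A panel whose ASM-positive amplicons bracket the printed
        ELK3 DMR coordinates yields a 225 bp DMR."""
        m = _matrix(
            ["het_no_asm", "solid_red", "het_no_asm"],
            starts=[96_616_800, 96_617_249, 96_617_600],
        )
        # make the red amplicon end at the printed right edge
        m.amplicons[1] = ("a1", GenomicInterval("chr12", 96_617_249, 96_617_474))
        m.amplicons[0] = ("a0", GenomicInterval("chr12", 96_616_800, 96_617_100))
        m.amplicons[2] = ("a2", GenomicInterval("chr12", 96_617_600, 96_617_900))
        (dmr,) = delineate_dmr(m)
        assert dmr.interval == GenomicInterval("chr12", 96_617_249, 96_617_474)
        assert dmr.interval.length == 225

    def test_runs_merged_across_tissues(self):
        m = _matrix(["solid_red", "solid_red", "het_no_asm"], tissues=("PBL", "liver"))
        # liver red only at a1..a2 -> overlapping a1 merges both runs
        m.cells[("a0", "liver")] = TissueCell("a0", "liver", 2, None, None, "het_no_asm")
        m.cells[("a2", "liver")] = TissueCell("a2", "liver", 2, 0.5, 1.0, "solid_red")
        (dmr,) = delineate_dmr(m)
        assert dmr.amplicon_ids == ("a0", "a1", "a2")
        assert dmr.tissues == ("PBL", "liver") or set(dmr.tissues) == {"PBL", "liver"}

    def test_empty_matrix(self):
        assert delineate_dmr(AsmCallMatrix([], [], {})) == []

    def test_annotate_dmr_flags(self):
        (dmr,) = delineate_dmr(_matrix(["solid_red"]))
        peaks = [GenomicInterval("chr1", 1100, 1200)]
        cgis = [GenomicInterval("chr1", 50_000, 51_000)]
        ann = annotate_dmr(dmr, peaks, cgis)
        assert ann.ctcf_overlap is True and ann.cgi_overlap is False


def test_planted_asm_recovery_small():
    """The planted amplicon is recovered as solid_red with no false red
    flanks (small-replicate version of the full calibration sweep)."""
    from asmscope.calibration import asm_power_and_dmr_recovery

    out = asm_power_and_dmr_recovery(n_reps=25, seed=17)
    assert out["solid_red_rate"] >= 0.95
    assert out["flank_false_red_rate"] == 0.0
    assert out["dmr_within_one_amplicon_rate"] >= 0.95
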