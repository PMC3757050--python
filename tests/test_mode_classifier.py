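import math

import numpy as np
import pytest

from asmscope.asm_stats import AsmResult
from asmscope.core_model import Thresholds
from asmscope.mode_classifier import (
    HaplotypeEvidence,
    TrioEvidence,
    TrioResult,
    analyze_trios,
    classify_locus,
    infer_parental_origin,
    reciprocal_cross_decomposition,
    score_haplotype_dependence,
    score_imprinting,
    score_imprinting_counts,
)


class TestParentalOrigin:
    def test_forced_assignment(self):
        call = infer_parental_origin(("G", "G"), ("A", "A"), ("A", "G"))
        assert call.status == "assigned"
        assert (call.maternal_allele, call.paternal_allele) == ("G", "A")

    def test_double_het_uninformative(self):
        assert infer_parental_origin(("A", "G"), ("A", "G"), ("A", "G")).status == "uninformative"

    def test_mendelian_error(self):
        assert infer_parental_origin(("A", "A"), ("A", "A"), ("A", "G")).status == "mendelian_error"

    def test_exhaustive_against_enumeration_oracle(self):
        from asmscope.calibration import mendelian_exhaustive_check

        n_ok, total = mendelian_exhaustive_check()
        assert (n_ok, total) == (27, 27)


class TestImprintingScore:
    @pytest.mark.parametrize(
        "nm,np_,chi2,p",
        [(13, 0, 13.0, 0.000311), (10, 0, 10.0, 0.001565), (5, 5, 0.0, 1.0)],
    )
    def test_counts(self, nm, np_, chi2, p):
        stat, pval, _ = score_imprinting_counts(nm, np_)
        assert stat == pytest.approx(chi2)
        assert pval == pytest.approx(p, abs=5e-7)

    def test_p_equals_erfc_closed_form(self):
        for nm, np_ in [(13, 0), (10, 0), (7, 3), (6, 6), (20, 1)]:
            chi2, p, _ = score_imprinting_counts(nm, np_)
            assert p == pytest.approx(math.erfc(math.sqrt(chi2 / 2)), abs=1e-9)

    def test_trio_result_aggregation(self):
        trios = [TrioResult(f"c{i}", "A", "G", "maternal") for i in range(4)] + [
            TrioResult("c9", None, None, "uninformative"),
            TrioResult("c10", "A", "G", "none"),
        ]
        ev = score_imprinting(trios)
        assert ev.n_informative == 4 and ev.n_maternal == 4
        assert ev.direction == "maternal"

    def test_zero_informative(self):
        ev = score_imprinting([TrioResult("c", None, None, "uninformative")])
        assert ev.chi2_p is None and ev.n_informative == 0


def _asm(sample, hyper, significant=True):
    delta = 0.7 if hyper == "G" else -0.7
    return AsmResult(sample, -delta, 0.001, 30, 30, hyper, significant)


class TestHaplotypeScore:
    def test_full_concordance(self):
        ev = score_haplotype_dependence({f"s{i}": _asm(f"s{i}", "G") for i in range(20)})
        assert ev.concordance == 1.0 and ev.concordant_allele == "G"
        assert ev.binomial_p < 1e-4

    def test_balanced_split(self):
        results = {f"s{i}": _asm(f"s{i}", "G" if i < 10 else "A") for i in range(20)}
        ev = score_haplotype_dependence(results)
        assert ev.concordance == 0.5
        assert ev.binomial_p == pytest.approx(1.0)

    def test_homozygote_consistency(self):
        results = {f"s{i}": _asm(f"s{i}", "G") for i in range(5)}
        ev = score_haplotype_dependence(results, {"G": 0.8, "A": 0.1})
        assert ev.homozygote_consistency is True
        ev = score_haplotype_dependence(results, {"G": 0.1, "A": 0.8})
        assert ev.homozygote_consistency is False

    def test_single_sample_undefined(self):
        ev = score_haplotype_dependence({"s0": _asm("s0", "G")})
        assert ev.concordance is None and ev.binomial_p is None


class TestClassifyLocus:
    def test_imprinted_pattern(self, th):
        haplo = HaplotypeEvidence(11, 0.55, "G", 0.82, None)
        trio = TrioEvidence(13, 13, 0, 13.0, 0.000311, "maternal")
        assert classify_locus(haplo, trio, th).mode == "imprinted_maternal"

    def test_haplotype_pattern_without_trios(self, th):
        haplo = HaplotypeEvidence(20, 1.0, "G", 2e-6, True)
        assert classify_locus(haplo, None, th).mode == "haplotype_dependent"

    def test_single_het_sample_ambiguous(self, th):
        haplo = HaplotypeEvidence(1, None, None, None, None)
        assert classify_locus(haplo, None, th).mode == "ambiguous"

    def test_no_asm_is_none(self, th):
        assert classify_locus(None, None, th, asm_present=False).mode == "none"

    def test_too_few_trios_ambiguous(self, th):
        trio = TrioEvidence(2, 2, 0, 2.0, 0.157, "maternal")
        assert classify_locus(None, trio, th).mode == "ambiguous"


class TestTrioPipeline:
    def test_imprinted_cohort_all_maternal(self, th):
        from asmscope.simdata import make_scenario, simulate_trio_cohort

        scenario = make_scenario("imprinted_maternal")
        table, pedigree, _ = simulate_trio_cohort(scenario, 15, 90, seed=21)
        by_ind: dict = {}
        for read in table.reads:
            by_ind.setdefault(read.individual_id, []).append(read)
        trios, n_err = analyze_trios(by_ind, pedigree, scenario.snp, th)
        ev = score_imprinting(trios)
        assert n_err == 0
        assert ev.n_informative >= 3
        assert ev.n_paternal == 0 and ev.direction == "maternal"

    def test_mendelian_error_excluded(self, th):
        import pandas as pd

        from tests.conftest import make_read

        reads = {
            "m": [make_read("A", "UUUU", sample_id="m") for _ in range(20)],
            "f": [make_read("A", "UUUU", sample_id="f") for _ in range(20)],
            "c": [make_read("A", "MMMM", sample_id="c") for _ in range(10)]
            + [make_read("G", "UUUU", sample_id="c") for _ in range(10)],
        }
        ped = pd.DataFrame([{"offspring_id": "c", "mother_id": "m", "father_id": "f"}])
        from asmscope.core_model import SnpVariant

        snp = SnpVariant("rs1", "chr1", 1005, "A", "G")
        trios, n_err = analyze_trios(reads, ped, snp, th)
        assert n_err == 1 and trios == []


class TestReciprocalCross:
    def test_parameter_recovery(self):
        from asmscope.simdata import cross_clone_frame, simulate_reciprocal_cross

        table, labels, _ = simulate_reciprocal_cross(0.3, 0.0, 8, depth=60, seed=31)
        out = reciprocal_cross_decomposition(cross_clone_frame(table, labels))
        assert out["strain_effect"] == pytest.approx(0.3, abs=0.05)
        assert out["parent_effect"] == pytest.approx(0.0, abs=0.05)
        assert out["strain_p"] < 0.001

    def test_null_effects(self):
        from asmscope.simdata import cross_clone_frame, simulate_reciprocal_cross

        table, labels, _ = simulate_reciprocal_cross(0.0, 0.0, 8, depth=40, seed=32)
        out = reciprocal_cross_decomposition(cross_clone_frame(table, labels))
        assert abs(out["strain_effect"]) < 0.05 and abs(out["parent_effect"]) < 0.05
        assert out["strain_p"] > 0.05 and out["parent_p"] > 0.05

    def test_both_effects_recovered(self):
        from asmscope.simdata import cross_clone_frame, simulate_reciprocal_cross

        table, labels, _ = simulate_reciprocal_cross(0.2, 0.1, 10, depth=60, seed=33)
        out = reciprocal_cross_decomposition(cross_clone_frame(table, labels))
        assert out["strain_effect"] == pytest.approx(0.2, abs=0.05)
        assert out["parent_effect"] == pytest.approx(0.1, abs=0.05)

    def test_single_direction_refused(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "direction": ["B6xCAST"] * 4,
                "strain": ["B6", "CAST"] * 2,
                "parent": ["maternal", "paternal"] * 2,
                "meth_frac": [0.1, 0.5, 0.2, 0.6],
            }
        )
        with pytest.raises(ValueError, match="confounded"):
            reciprocal_cross_decomposition(df)


def test_classifier_recovery_small():
    """Verdicts match the simulated truth on a small sweep per mode
    (the full 200-locus sweep runs in the acceptance suite)."""
    from asmscope.calibration import classifier_recovery

    acc = classifier_recovery(n_loci=20, seed=41)
    assert acc["imprinted_maternal"] >= 0.9
    assert acc["haplotype_dependent"] >= 0.9
    assert acc["null"] >= 0.9
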