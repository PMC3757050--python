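import pytest

from asmscope.amplicon_design import (
    DesignConstraints,
    convert_and_mask,
    design_panel,
    enumerate_primer_pairs,
    offtarget_scan,
    select_amplicons,
)
from asmscope.calibration import toy_design_genome
from asmscope.core_model import SnpVariant


class TestConvertAndMask:
    def test_conversion_rule(self):
        t = convert_and_mask({"c1": "ACGTCT"}, [])["c1"]
        assert t["top"].seq == "AYGTTT"
        # bottom strand: revcomp AGACGT -> converted AGAYGT
        assert t["bottom"].seq == "AGAYGT"

    def test_common_snp_masked(self):
        snps = [SnpVariant("rs1", "c1", 3, "T", "A", het_freq=0.05)]
        t = convert_and_mask({"c1": "ACGTCT"}, snps)["c1"]
        assert t["top"].seq[3] == "N"

    def test_rare_snp_unmasked(self):
        snps = [SnpVariant("rs1", "c1", 3, "T", "A", het_freq=0.005)]
        t = convert_and_mask({"c1": "ACGTCT"}, snps)["c1"]
        assert t["top"].seq == "AYGTTT"

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            convert_and_mask({"c1": "ACZT"}, [])

    def test_bottom_coordinates_round_trip(self):
        t = convert_and_mask({"c1": "ACGTCTAA"}, [])["c1"]["bottom"]
        assert t.to_genome(0, 3) == (5, 8)


@pytest.fixture(scope="module")
def toy():
    genome, snps, cpgs, regions = toy_design_genome(seed=1)
    return genome, snps, cpgs, regions


@pytest.fixture(scope="module")
def toy_templates(toy):
    genome, snps, _, _ = toy
    return convert_and_mask(genome, snps)


class TestEnumeration:
    def test_all_pairs_respect_primer_and_size_constraints(self, toy, toy_templates):
        genome, snps, cpgs, regions = toy
        c = DesignConstraints()
        region = regions[0]
        pairs = enumerate_primer_pairs(
            toy_templates["chrT"]["top"], (region.start, region.end), c
        )
        assert pairs
        for p in pairs:
            assert c.tm_range[0] <= p.tm_forward <= c.tm_range[1]
            assert c.tm_range[0] <= p.tm_reverse <= c.tm_range[1]
            assert c.gc_range[0] <= p.gc_forward <= c.gc_range[1]
            assert p.cpgs_forward <= c.max_cpgs_per_primer
            assert p.cpgs_reverse <= c.max_cpgs_per_primer
            assert c.amplicon_size[0] <= p.size <= c.amplicon_size[1]
            assert "N" not in p.forward and "N" not in p.reverse

    def test_short_region_yields_nothing(self, toy_templates):
        assert enumerate_primer_pairs(toy_templates["chrT"]["top"], (0, 150)) == []


class TestOfftarget:
    def test_unique_target_passes(self, toy, toy_templates):
        genome, snps, cpgs, regions = toy
        region = regions[0]
        pairs = enumerate_primer_pairs(
            toy_templates["chrT"]["top"], (region.start, region.end)
        )
        ok, hits = offtarget_scan(pairs[0], toy_templates)
        assert ok and hits == []

    def test_duplicated_target_fails(self, toy):
        genome, snps, cpgs, regions = toy
        region = regions[0]
        seq = genome["chrT"]
        dup = seq + seq[region.start : region.end]
        templates = convert_and_mask({"chrT": dup}, snps)
        pairs = enumerate_primer_pairs(
            templates["chrT"]["top"], (region.start, region.end)
        )
        ok, hits = offtarget_scan(pairs[0], templates)
        assert not ok and len(hits) >= 1

    def test_three_mismatches_ignored(self, toy, toy_templates):
        """A decoy copy of the product with three mismatches in each
        primer site is not an off-target hit."""
        genome, snps, cpgs, regions = toy
        region = regions[0]
        pairs = enumerate_primer_pairs(
            toy_templates["chrT"]["top"], (region.start, region.end)
        )
        pair = pairs[0]
        seq = genome["chrT"]
        product = list(seq[pair.product.start : pair.product.end])
        flip = {"A": "T", "T": "A", "G": "T", "C": "A"}
        for offset in (1, 4, 7):  # 3 internal mismatches in the forward site
            product[offset] = flip[product[offset]]
            product[-2 - offset] = flip[product[-2 - offset]]
        templates = convert_and_mask({"chrT": seq + "".join(product)}, snps)
        ok, _ = offtarget_scan(pair, templates)
        assert ok


class TestSelection:
    def test_min_cpgs_and_snp_het_filters(self, toy, toy_templates):
        genome, snps, cpgs, regions = toy
        region = regions[0]
        c = DesignConstraints()
        pairs = enumerate_primer_pairs(
            toy_templates["chrT"]["top"], (region.start, region.end), c
        )
        # with only 3 CpGs declared, nothing passes
        sparse = {"chrT": cpgs["chrT"][:3]}
        with pytest.warns(UserWarning, match="no amplicon"):
            assert select_amplicons(pairs, snps, sparse, c) == []
        # with the SNP below the heterozygosity floor, nothing passes
        weak = [
            SnpVariant(s.id, s.chrom, s.pos, s.allele_a, s.allele_b, 0.19)
            for s in snps
        ]
        with pytest.warns(UserWarning, match="no amplicon"):
            assert select_amplicons(pairs, weak, cpgs, c) == []
        kept = select_amplicons(pairs, snps, cpgs, c)
        assert kept
        assert all(p.n_cpgs_covered >= c.min_amplicon_cpgs for p in kept)

    def test_ranking_prefers_fewer_primer_cpgs_then_preferred_size(self, toy, toy_templates):
        genome, snps, cpgs, regions = toy
        region = regions[0]
        c = DesignConstraints()
        pairs = enumerate_primer_pairs(
            toy_templates["chrT"]["top"], (region.start, region.end), c
        )
        kept = select_amplicons(pairs, snps, cpgs, c)
        keys = [
            (p.cpgs_forward + p.cpgs_reverse, 0 if 200 <= p.size <= 450 else 1)
            for p in kept
        ]
        assert keys == sorted(keys)


def test_design_panel_deterministic_and_sound(toy):
    genome, snps, cpgs, regions = toy
    c = DesignConstraints()
    panel = design_panel(genome, snps, cpgs, regions[:1], c)
    assert panel
    assert panel == design_panel(genome, snps, cpgs, regions[:1], c)
    templates = convert_and_mask(genome, snps, c)
    for pair in panel:
        ok, _ = offtarget_scan(pair, templates, c)
        assert ok
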