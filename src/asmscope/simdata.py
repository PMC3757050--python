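"""Synthetic phased bisulfite reads, trios, reciprocal crosses and
genome-scale CpG tables with known ground truth.

The generators emulate the study design at every pipeline stage: long
amplicon reads carrying an index-SNP base plus a per-CpG methylation
vector; imprinted loci (one parental allele hypermethylated regardless of
haplotype), haplotype-dependent loci (a fixed nucleotide allele
hypermethylated in every carrier) and null loci; mother-father-offspring
trios with Mendelian transmission; reciprocal inter-strain crosses with
additive strain and parent effects; and a genome-scale per-CpG read-count
table laid out in a synthetic gene/CGI geography with optionally planted
CTCF enrichment.  Noise is modeled as per-call bisulfite conversion
failure (a true U reads M) and per-call sequencing error (any call flips;
an SNP base is replaced by a random other base).

Defaults mirror the study conditions: read depth 90 per sample per
amplicon, ≥4 CpGs per amplicon, index-SNP heterozygosity 0.5, allelic
methylation contrast 0.9 vs 0.05.  Conversion-failure (0.005) and
sequencing-error (0.001) rates are plausible for the platforms and are
config-exposed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import GenomicInterval, SnpVariant
from .io_formats import AmpliconDef, GeneRecord, ReadTable
from .allele_methylation import BisRead

__all__ = [
    "LocusScenario",
    "SimTruth",
    "make_scenario",
    "simulate_locus",
    "simulate_trio_cohort",
    "simulate_reciprocal_cross",
    "cross_clone_frame",
    "simulate_wgbs_table",
    "bisulfite_convert",
    "DEFAULT_CLASS_MIX",
    "DEFAULT_CONTEXT_MIX",
]

logger = logging.getLogger(__name__)

MODES = ("imprinted_maternal", "imprinted_paternal", "haplotype_dependent", "null")

#: genome-scale CpG class proportions observed in the H1 hES reference
#: analysis this table emulates (ASM 79,365 / full 200,318 / partial
#: 232,724 / unmethylated 1,774 of 514,181 tested CpGs)
DEFAULT_CLASS_MIX = {"asm": 0.1543, "full": 0.3896, "partial": 0.4526, "unmeth": 0.0035}

DEFAULT_CONTEXT_MIX = {
    "intergenic": 0.40,
    "intragenic": 0.35,
    "promoter": 0.10,
    "cgi": 0.08,
    "promoter_cgi": 0.07,
}


@dataclass(frozen=True)
class LocusScenario:
    """Ground-truth behavior of one simulated locus.

    ``meth_p_hyper``/``meth_p_hypo`` are the per-CpG methylation
    probabilities of the hyper- and hypomethylated allele.  In tissues
    outside ``tissue_specific`` (when set) both alleles use
    ``baseline_p`` (default: the hypomethylated probability).
    """

    mode: str
    snp: SnpVariant
    amplicon: AmpliconDef
    meth_p_hyper: float
    meth_p_hypo: float
    tissues: tuple[str, ...] = ("PBL",)
    tissue_specific: tuple[str, ...] | None = None
    baseline_p: float | None = None
    hyper_allele: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        for p in (self.meth_p_hyper, self.meth_p_hypo):
            if not 0.0 <= p <= 1.0:
                raise ValueError("methylation probabilities must lie in [0,1]")
        if self.mode == "null" and self.meth_p_hyper != self.meth_p_hypo:
            raise ValueError("null mode requires equal allele methylation")
        if self.mode == "haplotype_dependent":
            if self.hyper_allele not in self.snp.alleles:
                raise ValueError("haplotype mode needs hyper_allele ∈ SNP alleles")

    @property
    def baseline(self) -> float:
        return self.meth_p_hypo if self.baseline_p is None else self.baseline_p


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset."""

    mode: str
    genotypes: dict[str, tuple[str, str]] = field(default_factory=dict)
    #: per individual: (maternal base, paternal base); copy 0 is maternal
    origins: dict[str, tuple[str, str]] = field(default_factory=dict)
    #: per sample: 0/1 copy index actually sequenced in each read, in table order
    read_alleles: dict[str, np.ndarray] = field(default_factory=dict)
    pedigree: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def make_scenario(
    mode: str,
    n_cpgs: int = 8,
    meth_p_hyper: float = 0.90,
    meth_p_hypo: float = 0.05,
    het_freq: float = 0.5,
    tissues: tuple[str, ...] = ("PBL",),
    tissue_specific: tuple[str, ...] | None = None,
    chrom: str = "chrS",
    start: int = 10_000,
    amplicon_id: str = "amp1",
) -> LocusScenario:
    """Convenience constructor for a one-amplicon locus scenario."""
    snp = SnpVariant("rsSIM", chrom, start + 5, "A", "G", het_freq=het_freq)
    cpgs = tuple(start + 20 + 12 * i for i in range(n_cpgs))
    amp = AmpliconDef(
        amplicon_id=amplicon_id,
        interval=GenomicInterval(chrom, start, cpgs[-1] + 20),
        cpg_positions=cpgs,
        snp_id=snp.id,
    )
    if mode == "null":
        meth_p_hyper = meth_p_hypo = 0.5 if meth_p_hyper != meth_p_hypo else meth_p_hyper
    return LocusScenario(
        mode=mode,
        snp=snp,
        amplicon=amp,
        meth_p_hyper=meth_p_hyper,
        meth_p_hypo=meth_p_hypo,
        tissues=tissues,
        tissue_specific=tissue_specific,
        hyper_allele="G" if mode == "haplotype_dependent" else None,
    )


def _allele_freq(het_freq: float) -> float:
    # invert h = 2q(1-q); h <= 0.5 for a biallelic SNP
    if not 0.0 < het_freq <= 0.5:
        raise ValueError("het_freq must lie in (0, 0.5] under Hardy–Weinberg")
    return (1.0 - np.sqrt(1.0 - 2.0 * het_freq)) / 2.0


def _copy_meth_probs(
    scenario: LocusScenario, bases: tuple[str, str], tissue: str, rng: np.random.Generator
) -> tuple[float, float]:
    """Methylation probability of each allele copy (copy 0 is maternal)."""
    active = scenario.tissue_specific is None or tissue in scenario.tissue_specific
    if not active:
        return (scenario.baseline, scenario.baseline)
    hi, lo = scenario.meth_p_hyper, scenario.meth_p_hypo
    if scenario.mode == "imprinted_maternal":
        return (hi, lo)
    if scenario.mode == "imprinted_paternal":
        return (lo, hi)
    if scenario.mode == "haplotype_dependent":
        return tuple(hi if b == scenario.hyper_allele else lo for b in bases)
    return (lo, lo)  # null


_OTHER_BASES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def _draw_sample_reads(
    scenario: LocusScenario,
    bases: tuple[str, str],
    probs: tuple[float, float],
    sample_id: str,
    individual_id: str,
    tissue: str,
    depth: int,
    conv_fail_rate: float,
    seq_error_rate: float,
    rng: np.random.Generator,
) -> tuple[list[BisRead], np.ndarray]:
    cpgs = scenario.amplicon.cpg_positions
    n_cpgs = len(cpgs)
    copy_idx = rng.integers(0, 2, size=depth)
    p = np.array(probs)[copy_idx]
    meth = rng.random((depth, n_cpgs)) < p[:, None]
    if conv_fail_rate > 0:
        meth |= rng.random((depth, n_cpgs)) < conv_fail_rate
    if seq_error_rate > 0:
        meth ^= rng.random((depth, n_cpgs)) < seq_error_rate
    base_err = rng.random(depth) < seq_error_rate
    reads = []
    for i in range(depth):
        base = bases[copy_idx[i]]
        if base_err[i]:
            base = rng.choice(_OTHER_BASES[base])
        reads.append(
            BisRead(
                sample_id=sample_id,
                tissue=tissue,
                individual_id=individual_id,
                amplicon_id=scenario.amplicon.amplicon_id,
                snp_calls={scenario.snp.id: base},
                cpg_calls={
                    pos: ("M" if meth[i, j] else "U") for j, pos in enumerate(cpgs)
                },
            )
        )
    return reads, copy_idx


def simulate_locus(
    scenario: LocusScenario,
    n_individuals: int,
    depth_per_amplicon: int = 90,
    conv_fail_rate: float = 0.005,
    seq_error_rate: float = 0.001,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ReadTable, SimTruth]:
    """Simulate phased reads for unrelated individuals at one locus.

    Genotypes are drawn under Hardy–Weinberg from the SNP's heterozygote
    frequency; each read samples one allele copy uniformly and carries that
    copy's SNP base plus Bernoulli CpG calls at the copy's methylation
    probability, then noise is applied per call.  Deterministic under seed.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if depth_per_amplicon < 1:
        raise ValueError("depth_per_amplicon must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    q = _allele_freq(scenario.snp.het_freq)
    truth = SimTruth(mode=scenario.mode)
    reads: list[BisRead] = []
    for i in range(n_individuals):
        ind = f"ind{i:03d}"
        bases = tuple(
            scenario.snp.allele_a if rng.random() < q else scenario.snp.allele_b
            for _ in range(2)
        )
        truth.genotypes[ind] = bases
        truth.origins[ind] = bases  # copy 0 maternal, copy 1 paternal
        for tissue in scenario.tissues:
            probs = _copy_meth_probs(scenario, bases, tissue, rng)
            sample_id = f"{ind}:{tissue}"
            sample_reads, copy_idx = _draw_sample_reads(
                scenario,
                bases,
                probs,
                sample_id,
                ind,
                tissue,
                depth_per_amplicon,
                conv_fail_rate,
                seq_error_rate,
                rng,
            )
            reads.extend(sample_reads)
            truth.read_alleles[sample_id] = copy_idx
    table = ReadTable(
        reads=reads, amplicons={scenario.amplicon.amplicon_id: scenario.amplicon}
    )
    return table, truth


def simulate_trio_cohort(
    scenario: LocusScenario,
    n_trios: int,
    depth_per_amplicon: int = 90,
    parent_depth: int = 30,
    conv_fail_rate: float = 0.005,
    seq_error_rate: float = 0.001,
    offspring_tissue: str = "placenta",
    parent_tissue: str = "PBL",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ReadTable, pd.DataFrame, SimTruth]:
    """Simulate mother-father-offspring trios with Mendelian transmission.

    Parental genotypes are drawn under Hardy–Weinberg; the offspring
    receives one fair-draw allele from each parent, with its maternal copy
    stored first.  Offspring reads are methylated by parental origin
    (imprinted modes) or allele identity (haplotype mode); parents carry
    the same locus biology in their own tissue, with an unknown (random)
    origin for imprinted parents.  Returns the read table, a pedigree
    table (offspring_id, mother_id, father_id) and the ground truth.
    """
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    q = _allele_freq(scenario.snp.het_freq)
    truth = SimTruth(mode=scenario.mode)
    reads: list[BisRead] = []
    ped_rows = []
    offspring_active = (
        scenario.tissue_specific is None or offspring_tissue in scenario.tissue_specific
    )
    if not offspring_active:
        warnings.warn(
            "trio offspring tissue lies outside the scenario's ASM-active set;"
            " parent-of-origin will not be recoverable",
            stacklevel=2,
        )
    for i in range(n_trios):
        mother, father, child = (f"trio{i:02d}{w}" for w in ("m", "f", "c"))
        m_bases = tuple(
            scenario.snp.allele_a if rng.random() < q else scenario.snp.allele_b
            for _ in range(2)
        )
        f_bases = tuple(
            scenario.snp.allele_a if rng.random() < q else scenario.snp.allele_b
            for _ in range(2)
        )
        maternal = m_bases[rng.integers(0, 2)]
        paternal = f_bases[rng.integers(0, 2)]
        c_bases = (maternal, paternal)
        truth.genotypes.update({mother: m_bases, father: f_bases, child: c_bases})
        truth.origins[child] = c_bases
        ped_rows.append({"offspring_id": child, "mother_id": mother, "father_id": father})
        for ind, bases, tissue, depth in (
            (mother, m_bases, parent_tissue, parent_depth),
            (father, f_bases, parent_tissue, parent_depth),
            (child, c_bases, offspring_tissue, depth_per_amplicon),
        ):
            if ind != child and scenario.mode.startswith("imprinted"):
                # the parents' own parental origins are unobserved
                pbases = bases if rng.integers(0, 2) == 0 else bases[::-1]
            else:
                pbases = bases
            probs = _copy_meth_probs(scenario, pbases, tissue, rng)
            if ind != child and scenario.mode.startswith("imprinted"):
                if pbases != bases:
                    probs = probs[::-1]
            sample_id = f"{ind}:{tissue}"
            sample_reads, copy_idx = _draw_sample_reads(
                scenario,
                bases,
                probs,
                sample_id,
                ind,
                tissue,
                depth,
                conv_fail_rate,
                seq_error_rate,
                rng,
            )
            reads.extend(sample_reads)
            truth.read_alleles[sample_id] = copy_idx
    pedigree = pd.DataFrame(ped_rows)
    truth.pedigree = pedigree
    table = ReadTable(
        reads=reads, amplicons={scenario.amplicon.amplicon_id: scenario.amplicon}
    )
    return table, pedigree, truth


#: pseudo-SNP distinguishing mouse strains in reciprocal-cross data
STRAIN_BASE = {"B6": "A", "CAST": "G"}


def simulate_reciprocal_cross(
    strain_effect: float,
    parent_effect: float,
    n_per_direction: int = 8,
    depth: int = 40,
    baseline: float = 0.30,
    n_cpgs: int = 8,
    conv_fail_rate: float = 0.005,
    seq_error_rate: float = 0.001,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ReadTable, pd.DataFrame, SimTruth]:
    """Simulate F1 samples from reciprocal inter-strain crosses.

    Both directions (B6 mother × CAST father and the reverse) are
    generated; each F1 carries one allele per strain, whose methylation
    probability is ``baseline`` plus additive strain (CAST − B6) and
    parent (maternal − paternal) shifts, clamped to [0, 1] (clamping is
    logged).  Returns the read table, a per-sample label table mapping
    each allele base to its strain and parent of origin, and the truth.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    snp = SnpVariant("strain", "chrM1", 1005, STRAIN_BASE["B6"], STRAIN_BASE["CAST"])
    cpgs = tuple(1020 + 12 * i for i in range(n_cpgs))
    amp = AmpliconDef("ampX", GenomicInterval("chrM1", 1000, cpgs[-1] + 20), cpgs, snp.id)
    scenario = LocusScenario(
        mode="null",
        snp=snp,
        amplicon=amp,
        meth_p_hyper=baseline,
        meth_p_hypo=baseline,
    )
    truth = SimTruth(mode="reciprocal_cross")
    reads: list[BisRead] = []
    label_rows = []
    for direction, (m_strain, f_strain) in (
        ("B6xCAST", ("B6", "CAST")),
        ("CASTxB6", ("CAST", "B6")),
    ):
        for i in range(n_per_direction):
            ind = f"{direction}_{i:02d}"
            bases = (STRAIN_BASE[m_strain], STRAIN_BASE[f_strain])  # maternal first
            probs = []
            for strain, parent in ((m_strain, "maternal"), (f_strain, "paternal")):
                p = (
                    baseline
                    + (strain_effect if strain == "CAST" else 0.0)
                    + (parent_effect if parent == "maternal" else 0.0)
                )
                if not 0.0 <= p <= 1.0:
                    logger.info("methylation probability %g clamped to [0,1]", p)
                    p = min(1.0, max(0.0, p))
                probs.append(p)
                label_rows.append(
                    {
                        "sample_id": f"{ind}:yolk_sac",
                        "direction": direction,
                        "allele_base": STRAIN_BASE[strain],
                        "strain": strain,
                        "parent": parent,
                    }
                )
            sample_id = f"{ind}:yolk_sac"
            sample_reads, copy_idx = _draw_sample_reads(
                scenario,
                bases,
                tuple(probs),
                sample_id,
                ind,
                "yolk_sac",
                depth,
                conv_fail_rate,
                seq_error_rate,
                rng,
            )
            reads.extend(sample_reads)
            truth.read_alleles[sample_id] = copy_idx
            truth.genotypes[ind] = bases
            truth.origins[ind] = bases
    truth.extra = {"strain_effect": strain_effect, "parent_effect": parent_effect}
    labels = pd.DataFrame(label_rows)
    return ReadTable(reads=reads, amplicons={amp.amplicon_id: amp}), labels, truth


def cross_clone_frame(table: ReadTable, labels: pd.DataFrame) -> pd.DataFrame:
    """Flatten reciprocal-cross reads to one row per clone with its
    methylated fraction, strain, parent and cross direction."""
    from .allele_methylation import read_meth_fraction

    key = {
        (r.sample_id, r.allele_base): (r.direction, r.strain, r.parent)
        for r in labels.itertuples()
    }
    rows = []
    for read in table.reads:
        base = next(iter(read.snp_calls.values()))
        lab = key.get((read.sample_id, base))
        if lab is None:  # sequencing-error base, unassignable
            continue
        frac = read_meth_fraction(read)
        if frac is None:
            continue
        direction, strain, parent = lab
        rows.append(
            {
                "sample_id": read.sample_id,
                "direction": direction,
                "strain": strain,
                "parent": parent,
                "meth_frac": frac,
            }
        )
    return pd.DataFrame(rows)


_CONTEXT_CHOICES = tuple(DEFAULT_CONTEXT_MIX)


def simulate_wgbs_table(
    n_cpgs: int,
    class_mix: dict[str, float] | None = None,
    ctcf_density: float = 0.30,
    planted_promoter_cgi_enrichment: float = 1.0,
    context_mix: dict[str, float] | None = None,
    depth_range: tuple[int, int] = (20, 60),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[GenomicInterval], list[GeneRecord], list[GenomicInterval], pd.DataFrame]:
    """Simulate a genome-scale per-CpG read-count table with geography.

    Each CpG occupies its own 10 kb tile of a synthetic chromosome, so the
    promoter (±1 kb), CGI-proximity (250 bp) and CTCF-window annotations
    of neighbouring CpGs cannot interfere.  Per CpG, a genomic context and
    a methylation class are drawn from the supplied mixes; methylated-read
    counts are drawn to land inside the class's fraction band; a CTCF peak
    is placed inside the CpG's 500 bp window with probability
    ``ctcf_density``, with the odds multiplied by
    ``planted_promoter_cgi_enrichment`` for ASM CpGs in promoter-CGI
    context.  Returns (counts table, CTCF peaks, genes, CGIs, truth).
    """
    if class_mix is None:
        class_mix = DEFAULT_CLASS_MIX
    if context_mix is None:
        context_mix = DEFAULT_CONTEXT_MIX
    for name, mix in (("class_mix", class_mix), ("context_mix", context_mix)):
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    tile = 10_000
    chrom = "chrW"
    classes = rng.choice(list(class_mix), size=n_cpgs, p=list(class_mix.values()))
    contexts = rng.choice(list(context_mix), size=n_cpgs, p=list(context_mix.values()))
    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=n_cpgs)
    r = planted_promoter_cgi_enrichment
    d = ctcf_density
    p_planted = r * d / (1.0 - d + r * d)
    records, truth_rows = [], []
    peaks: list[GenomicInterval] = []
    genes: list[GeneRecord] = []
    cgis: list[GenomicInterval] = []
    for i in range(n_cpgs):
        pos = i * tile + tile // 2
        ctx, cls, n = contexts[i], classes[i], int(depths[i])
        if ctx in ("promoter", "promoter_cgi"):
            tss = pos + 300
            iv = GenomicInterval(chrom, tss, tss + 2000)
            genes.append(GeneRecord(f"G{i}", iv, "+", tss))
        elif ctx == "intragenic":
            iv = GenomicInterval(chrom, pos - 3000, pos + 3000)
            genes.append(GeneRecord(f"G{i}", iv, "+", pos - 3000))
        if ctx in ("cgi", "promoter_cgi"):
            cgis.append(GenomicInterval(chrom, pos - 100, pos + 150))
        if cls == "full":
            n_meth = min(n, max(int(round(rng.uniform(0.93, 1.0) * n)), int(0.9 * n) + 1))
        elif cls == "unmeth":
            n_meth = int(round(rng.uniform(0.0, 0.07) * n))
            if n_meth / n >= 0.1:
                n_meth = 0
        elif cls == "partial":
            n_meth = int(round(rng.uniform(0.2, 0.8) * n))
            n_meth = min(max(n_meth, int(np.ceil(0.1 * n))), int(np.floor(0.9 * n)))
        else:  # asm: two alleles, one high one low
            n_meth = int(round(rng.uniform(0.4, 0.6) * n))
        asm_flag = cls == "asm"
        p_near = p_planted if (asm_flag and ctx == "promoter_cgi") else d
        near = rng.random() < p_near
        if near:
            peaks.append(GenomicInterval(chrom, pos - 180, pos - 60))
        records.append(
            {
                "chrom": chrom,
                "pos": pos,
                "n_meth": n_meth,
                "n_total": n,
                "asm_flag": asm_flag,
                "is_polymorphic": False,
            }
        )
        truth_rows.append(
            {"pos": pos, "true_class": cls, "true_context": ctx, "ctcf_near": near}
        )
    return (
        pd.DataFrame(records),
        sorted(peaks),
        sorted(genes, key=lambda g: g.interval.start),
        sorted(cgis),
        pd.DataFrame(truth_rows),
    )


def bisulfite_convert(
    seq: str,
    methylation_state_per_cpg: dict[int, bool] | None = None,
    conv_efficiency: float = 1.0,
    rng: np.random.Generator | None = None,
) -> str:
    """Apply the bisulfite conversion rule to a sequence.

    Every C outside a CpG converts to T.  The C of a CpG converts to T
    only if unmethylated *and* the conversion succeeds (probability
    ``conv_efficiency``); a failed conversion leaves C, which downstream
    reads as methylated.  ``methylation_state_per_cpg`` maps the index of
    a CpG's C in ``seq`` to True (methylated); unlisted CpGs are
    unmethylated.
    """
    if seq != seq.upper():
        warnings.warn("lowercase input sequence upcased", stacklevel=2)
        seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        pos = next(i for i, ch in enumerate(seq) if ch in bad)
        raise ValueError(f"invalid character {seq[pos]!r} at position {pos}")
    meth = methylation_state_per_cpg or {}
    rng = rng if rng is not None else np.random.default_rng()
    out = list(seq)
    for i, ch in enumerate(seq):
        if ch != "C":
            continue
        is_cpg = i + 1 < len(seq) and seq[i + 1] == "G"
        if not is_cpg:
            out[i] = "T"
        elif meth.get(i, False):
            out[i] = "C"
        elif conv_efficiency >= 1.0 or rng.random() < conv_efficiency:
            out[i] = "T"
        else:
            out[i] = "C"
    return "".join(out)
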