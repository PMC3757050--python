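"""Classify a locus's ASM as imprinted, haplotype-dependent or ambiguous.

Two independent lines of evidence are combined.  Across unrelated
heterozygous samples, haplotype-dependent ASM shows the *same* nucleotide
allele hypermethylated in every carrier (high concordance), while
imprinted ASM shows either allele hypermethylated depending on parental
origin (concordance at chance).  Trios of parents and offspring then test
parent-of-origin directly: each informative trio assigns the offspring's
hypermethylated allele to one parent, and the maternal/paternal counts are
tested against a 50:50 expectation by a df=1 chi-square goodness-of-fit
test without continuity correction (13:0 gives χ² = 13, p = 0.000311;
10:0 gives χ² = 10, p = 0.001565).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

from scipy import stats

from .asm_stats import AsmResult
from .core_model import Thresholds

__all__ = [
    "OriginCall",
    "TrioResult",
    "HaplotypeEvidence",
    "TrioEvidence",
    "LocusClassification",
    "infer_parental_origin",
    "score_imprinting",
    "score_imprinting_counts",
    "score_haplotype_dependence",
    "classify_locus",
    "genotype_bases",
    "analyze_trios",
    "reciprocal_cross_decomposition",
]


@dataclass(frozen=True)
class OriginCall:
    """Outcome of parental-origin inference for one offspring genotype."""

    status: str  # assigned | uninformative | mendelian_error
    maternal_allele: str | None = None
    paternal_allele: str | None = None


@dataclass(frozen=True)
class TrioResult:
    """Parent-of-origin call for one offspring sample."""

    offspring_sample: str
    maternal_allele: str | None
    paternal_allele: str | None
    hyper_parent: str  # maternal | paternal | none | uninformative

    def __post_init__(self) -> None:
        if self.hyper_parent in ("maternal", "paternal") and (
            self.maternal_allele is None or self.paternal_allele is None
        ):
            raise ValueError("hyper_parent set without an informative origin")


@dataclass(frozen=True)
class HaplotypeEvidence:
    """Concordance of the hypermethylated nucleotide across unrelated hets."""

    n_samples: int
    concordance: float | None
    concordant_allele: str | None
    binomial_p: float | None
    homozygote_consistency: bool | None


@dataclass(frozen=True)
class TrioEvidence:
    n_informative: int
    n_maternal: int
    n_paternal: int
    chi2_stat: float | None
    chi2_p: float | None
    direction: str | None


@dataclass(frozen=True)
class LocusClassification:
    """The imprinted / haplotype-dependent / ambiguous / none verdict."""

    mode: str
    concordance: float | None = None
    binomial_p: float | None = None
    chi2_stat: float | None = None
    chi2_p: float | None = None
    n_trios_informative: int = 0
    homozygote_consistency: bool | None = None
    tissue: str | None = None
    note: str = ""


def infer_parental_origin(
    mother_gt: tuple[str, str],
    father_gt: tuple[str, str],
    offspring_gt: tuple[str, str],
) -> OriginCall:
    """Assign each offspring allele to a parent, when unambiguous.

    Genotypes are unordered base pairs at one SNP.  The origin is assigned
    iff exactly one (maternal, paternal) labelling of the offspring's
    alleles is Mendelian-consistent; two consistent labellings are
    uninformative; zero is a Mendelian error.
    """
    mother, father = set(mother_gt), set(father_gt)
    a, b = offspring_gt
    assignments = {
        (m, p)
        for (m, p) in ((a, b), (b, a))
        if m in mother and p in father
    }
    if not assignments:
        return OriginCall("mendelian_error")
    if len(assignments) > 1:
        return OriginCall("uninformative")
    maternal, paternal = next(iter(assignments))
    return OriginCall("assigned", maternal_allele=maternal, paternal_allele=paternal)


def score_imprinting_counts(n_maternal: int, n_paternal: int) -> tuple[float, float, str | None]:
    """Chi-square goodness-of-fit of parent-of-origin counts against 50:50.

    df = 1, no continuity correction, upper-tail p.  Returns
    (chi2, p, majority direction).
    """
    n = n_maternal + n_paternal
    if n == 0:
        raise ValueError("no informative trios to test")
    e = n / 2.0
    chi2 = (n_maternal - e) ** 2 / e + (n_paternal - e) ** 2 / e
    p = float(stats.chi2.sf(chi2, df=1))
    if n_maternal > n_paternal:
        direction = "maternal"
    elif n_paternal > n_maternal:
        direction = "paternal"
    else:
        direction = None
    return chi2, p, direction


def score_imprinting(trios: list[TrioResult]) -> TrioEvidence:
    """Summarize trio parent-of-origin calls into imprinting evidence."""
    informative = [t for t in trios if t.hyper_parent in ("maternal", "paternal")]
    n_m = sum(t.hyper_parent == "maternal" for t in informative)
    n_p = sum(t.hyper_parent == "paternal" for t in informative)
    if not informative:
        return TrioEvidence(0, 0, 0, None, None, None)
    chi2, p, direction = score_imprinting_counts(n_m, n_p)
    return TrioEvidence(len(informative), n_m, n_p, chi2, p, direction)


def score_haplotype_dependence(
    het_results: dict[str, AsmResult],
    hom_profiles: dict[str, float] | None = None,
) -> HaplotypeEvidence:
    """Concordance of the hypermethylated nucleotide across unrelated hets.

    Only samples with significant ASM vote.  Concordance is the fraction
    of voters whose hypermethylated allele is the majority one, tested
    against 0.5 by a two-sided exact binomial test.  Homozygote
    consistency (when per-genotype net methylation is supplied) requires
    hom carriers of the majority hyper allele to show higher net
    methylation than hom carriers of the other allele.
    """
    voters = [
        r
        for r in het_results.values()
        if r.significant and r.hyper_allele is not None
    ]
    if len(voters) < 2:
        return HaplotypeEvidence(len(voters), None, None, None, None)
    counts: dict[str, int] = {}
    for r in voters:
        counts[r.hyper_allele] = counts.get(r.hyper_allele, 0) + 1
    allele, k = max(counts.items(), key=lambda kv: kv[1])
    n = len(voters)
    concordance = k / n
    binomial_p = float(stats.binomtest(k, n, 0.5).pvalue)
    consistency: bool | None = None
    if hom_profiles:
        other = next((a for a in counts if a != allele), None)
        hyper_net = hom_profiles.get(allele)
        other_net = hom_profiles.get(other) if other else None
        if other_net is None:
            # only one homozygous class observed; compare to the remaining key
            remaining = [v for kk, v in hom_profiles.items() if kk != allele]
            other_net = remaining[0] if remaining else None
        if hyper_net is not None and other_net is not None:
            consistency = hyper_net > other_net
    return HaplotypeEvidence(n, concordance, allele, binomial_p, consistency)


def classify_locus(
    haplo: HaplotypeEvidence | None,
    trio: TrioEvidence | None,
    th: Thresholds,
    asm_present: bool = True,
    tissue: str | None = None,
) -> LocusClassification:
    """Combine cohort concordance and trio tests into a locus verdict.

    ``none`` when the tissue shows no ASM.  ``haplotype_dependent`` when
    the concordance binomial test rejects chance and the concordance
    reaches the configured floor (default 0.9).  ``imprinted_<parent>``
    when the trio chi-square rejects 50:50 with at least
    ``imprint_min_trios`` informative trios and the cohort concordance is
    consistent with chance.  Conflicting strong evidence, or neither,
    yields ``ambiguous``.
    """
    common = dict(
        concordance=haplo.concordance if haplo else None,
        binomial_p=haplo.binomial_p if haplo else None,
        chi2_stat=trio.chi2_stat if trio else None,
        chi2_p=trio.chi2_p if trio else None,
        n_trios_informative=trio.n_informative if trio else 0,
        homozygote_consistency=haplo.homozygote_consistency if haplo else None,
        tissue=tissue,
    )
    if not asm_present:
        return LocusClassification(mode="none", **common)
    hap_fires = (
        haplo is not None
        and haplo.concordance is not None
        and haplo.binomial_p is not None
        and haplo.binomial_p < th.asm_alpha
        and haplo.concordance >= th.haplotype_concordance_min
    )
    concordance_chance = haplo is None or haplo.binomial_p is None or (
        haplo.binomial_p >= th.asm_alpha
    )
    imp_fires = (
        trio is not None
        and trio.chi2_p is not None
        and trio.chi2_p < th.asm_alpha
        and trio.n_informative >= th.imprint_min_trios
        and trio.direction is not None
        and concordance_chance
    )
    if hap_fires and imp_fires:
        return LocusClassification(
            mode="ambiguous", note="conflicting haplotype and trio evidence", **common
        )
    if hap_fires:
        return LocusClassification(mode="haplotype_dependent", **common)
    if imp_fires:
        return LocusClassification(mode=f"imprinted_{trio.direction}", **common)
    return LocusClassification(mode="ambiguous", **common)


def reciprocal_cross_decomposition(clones) -> dict[str, float]:
    """Decompose reciprocal-cross allele methylation into strain and
    parent-of-origin effects.

    ``clones`` is a DataFrame with one row per allele-specific bisulfite
    clone: columns ``direction``, ``strain`` (B6/CAST), ``parent``
    (maternal/paternal) and ``meth_frac``.  Effects are the CAST − B6 and
    maternal − paternal mean differences computed within each cross
    direction and averaged equally over the two directions, which cancels
    the confounding between the factors.  Welch t-tests per factor are
    run on the pooled per-clone values.  Both directions must be present.
    """
    directions = set(clones["direction"])
    if len(directions) < 2:
        raise ValueError(
            "both cross directions are required; with one direction the "
            "strain and parent effects are confounded"
        )
    strain_diffs, parent_diffs = [], []
    for direction in sorted(directions):
        sub = clones[clones["direction"] == direction]
        strain_diffs.append(
            sub[sub["strain"] == "CAST"]["meth_frac"].mean()
            - sub[sub["strain"] == "B6"]["meth_frac"].mean()
        )
        parent_diffs.append(
            sub[sub["parent"] == "maternal"]["meth_frac"].mean()
            - sub[sub["parent"] == "paternal"]["meth_frac"].mean()
        )
    cast = clones[clones["strain"] == "CAST"]["meth_frac"]
    b6 = clones[clones["strain"] == "B6"]["meth_frac"]
    mat = clones[clones["parent"] == "maternal"]["meth_frac"]
    pat = clones[clones["parent"] == "paternal"]["meth_frac"]
    strain_p = float(stats.ttest_ind(cast, b6, equal_var=False).pvalue)
    parent_p = float(stats.ttest_ind(mat, pat, equal_var=False).pvalue)
    return {
        "strain_effect": sum(strain_diffs) / len(strain_diffs),
        "parent_effect": sum(parent_diffs) / len(parent_diffs),
        "strain_p": strain_p,
        "parent_p": parent_p,
    }


def genotype_bases(call, snp) -> tuple[str, str] | None:
    """Unordered base pair implied by a GenotypeCall, or None for no_call."""
    if call.status == "het":
        return (snp.allele_a, snp.allele_b)
    if call.status == "hom_a":
        return (snp.allele_a, snp.allele_a)
    if call.status == "hom_b":
        return (snp.allele_b, snp.allele_b)
    return None


def analyze_trios(
    reads_by_individual: dict[str, list],
    pedigree,
    snp,
    th: Thresholds,
    exclude_positions: frozenset[int] | set[int] = frozenset(),
) -> tuple[list[TrioResult], int]:
    """Genotype each trio member from its reads, infer parental origin,
    and score the offspring's hypermethylated allele by parent.

    ``pedigree`` is a table with offspring_id / mother_id / father_id
    columns.  Mendelian-inconsistent trios are excluded and counted in
    the second return value.  The offspring's hyper_parent is set only
    when its origin is informative and it shows significant ASM of at
    least ``asm_delta_min``.
    """
    from .allele_methylation import call_sample_genotype, split_reads_by_allele
    from .asm_stats import asm_test_sample

    results: list[TrioResult] = []
    n_mendelian_errors = 0
    for row in pedigree.itertuples():
        bases = {}
        complete = True
        for ind in (row.mother_id, row.father_id, row.offspring_id):
            gt = call_sample_genotype(reads_by_individual.get(ind, []), snp, th)
            b = genotype_bases(gt, snp)
            if b is None:
                complete = False
                break
            bases[ind] = b
        if not complete:
            results.append(TrioResult(row.offspring_id, None, None, "uninformative"))
            continue
        origin = infer_parental_origin(
            bases[row.mother_id], bases[row.father_id], bases[row.offspring_id]
        )
        if origin.status == "mendelian_error":
            n_mendelian_errors += 1
            continue
        if origin.status != "assigned" or origin.maternal_allele == origin.paternal_allele:
            results.append(TrioResult(row.offspring_id, None, None, "uninformative"))
            continue
        reads = reads_by_individual[row.offspring_id]
        ra, rb, _ = split_reads_by_allele(reads, snp)
        if not ra or not rb:
            results.append(TrioResult(row.offspring_id, None, None, "uninformative"))
            continue
        res = asm_test_sample(
            ra,
            rb,
            th,
            sample_id=row.offspring_id,
            alleles=snp.alleles,
            exclude_positions=exclude_positions,
        )
        if res.significant and abs(res.delta) >= th.asm_delta_min and res.hyper_allele:
            hyper_parent = (
                "maternal" if res.hyper_allele == origin.maternal_allele else "paternal"
            )
        else:
            hyper_parent = "none"
        results.append(
            TrioResult(
                row.offspring_id,
                origin.maternal_allele,
                origin.paternal_allele,
                hyper_parent,
            )
        )
    return results, n_mendelian_errors


def all_genotype_triples(alleles: tuple[str, str] = ("A", "G")):
    """All 27 unordered biallelic genotype triples (mother, father, child);
    used by the exhaustive Mendelian consistency check."""
    gts = list(combinations_with_replacement(alleles, 2))  # AA, AG, GG
    for m in gts:
        for f in gts:
            for c in gts:
                yield m, f, c
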