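"""Allele-level methylation calling from phased bisulfite reads.

Each long bisulfite read covers one amplicon and carries both the base call
at the amplicon's index SNP and an ordered vector of per-CpG methylation
calls, so reads phase themselves: once a sample is genotyped heterozygous,
its reads partition cleanly into the two allele-specific clone sets and each
allele yields its own methylation profile.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from statistics import fmean

from .core_model import SnpVariant, Thresholds

__all__ = [
    "MISSING",
    "BisRead",
    "AlleleProfile",
    "GenotypeCall",
    "read_meth_fraction",
    "call_sample_genotype",
    "split_reads_by_allele",
    "allele_profile",
    "net_methylation",
]

logger = logging.getLogger(__name__)

#: methylation-call codes: M methylated, U unmethylated, "." missing
MISSING = "."
METH_CODES = frozenset({"M", "U", MISSING})


@dataclass(frozen=True, slots=True)
class BisRead:
    """One phased bisulfite read — the atomic evidence unit.

    ``snp_calls`` maps SNP id to the base read at that SNP; ``cpg_calls``
    maps the genomic position of each covered CpG (the C) to its call.
    """

    sample_id: str
    amplicon_id: str
    snp_calls: dict[str, str]
    cpg_calls: dict[int, str]
    tissue: str = ""
    individual_id: str = ""

    def __post_init__(self) -> None:
        if not self.cpg_calls:
            raise ValueError("a read must carry at least one CpG call")
        bad = {c for c in self.cpg_calls.values() if c not in METH_CODES}
        if bad:
            raise ValueError(f"unknown methylation code(s): {sorted(bad)}")


def read_meth_fraction(
    read: BisRead, exclude_positions: frozenset[int] | set[int] = frozenset()
) -> float | None:
    """Fraction of informative CpG calls in one read that are methylated.

    Missing calls and calls at excluded (polymorphic) CpG positions enter
    neither numerator nor denominator.  None when no informative call is
    left.
    """
    m = u = 0
    for pos, call in read.cpg_calls.items():
        if pos in exclude_positions or call == MISSING:
            continue
        if call == "M":
            m += 1
        else:
            u += 1
    if m + u == 0:
        return None
    return m / (m + u)


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample genotype at one amplicon's index SNP."""

    status: str  # het | hom_a | hom_b | no_call
    n_reads: int
    minor_frac: float
    reason: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.minor_frac <= 0.5:
            raise ValueError("minor_frac must lie in [0, 0.5]")


@dataclass(frozen=True)
class AlleleProfile:
    """Methylation summary of one allele's clone set at one amplicon."""

    allele: str
    n_reads: int
    per_cpg_frac: dict[int, float | None]
    mean_frac: float | None


def call_sample_genotype(
    reads: list[BisRead], snp: SnpVariant, th: Thresholds
) -> GenotypeCall:
    """Genotype one sample at the index SNP from its phased reads.

    Requires ``genotype_min_reads`` usable reads; the sample is heterozygous
    iff the minor allele is carried by at least ``genotype_minor_frac`` of
    them (a tie at exactly the threshold counts as het).  Reads whose base
    at the SNP is not one of the two declared alleles are discordant: they
    are excluded from the counts and logged.
    """
    counts: Counter[str] = Counter()
    discordant = 0
    for read in reads:
        base = read.snp_calls.get(snp.id)
        if base is None:
            continue
        if base in snp.alleles:
            counts[base] += 1
        else:
            discordant += 1
    if discordant:
        logger.info(
            "genotyping %s: %d read(s) with discordant base at %s excluded",
            reads[0].sample_id if reads else "?",
            discordant,
            snp.id,
        )
    n = counts[snp.allele_a] + counts[snp.allele_b]
    if n == 0:
        return GenotypeCall("no_call", 0, 0.0, reason=f"SNP {snp.id} absent from reads")
    minor_frac = min(counts[snp.allele_a], counts[snp.allele_b]) / n
    if n < th.genotype_min_reads:
        return GenotypeCall("no_call", n, minor_frac, reason="insufficient reads")
    if minor_frac >= th.genotype_minor_frac:
        return GenotypeCall("het", n, minor_frac)
    major = "hom_a" if counts[snp.allele_a] >= counts[snp.allele_b] else "hom_b"
    return GenotypeCall(major, n, minor_frac)


def split_reads_by_allele(
    reads: list[BisRead], snp: SnpVariant
) -> tuple[list[BisRead], list[BisRead], list[BisRead]]:
    """Partition phased reads by the base at the index SNP.

    Returns ``(reads_a, reads_b, discarded)`` where discarded holds reads
    with a missing or discordant SNP base.
    """
    reads_a: list[BisRead] = []
    reads_b: list[BisRead] = []
    discarded: list[BisRead] = []
    for read in reads:
        base = read.snp_calls.get(snp.id)
        if base == snp.allele_a:
            reads_a.append(read)
        elif base == snp.allele_b:
            reads_b.append(read)
        else:
            discarded.append(read)
    return reads_a, reads_b, discarded


def allele_profile(
    reads: list[BisRead],
    allele: str = "",
    exclude_positions: frozenset[int] | set[int] = frozenset(),
) -> AlleleProfile:
    """Per-CpG and mean methylation fractions of one clone set.

    Per-CpG fraction is M/(M+U) over reads, ignoring missing calls; a CpG
    with zero informative calls is reported as None.  ``mean_frac`` is the
    mean over reads of each read's own methylated fraction (clones weighted
    equally, regardless of how many CpGs each covers).  Polymorphic CpGs
    are excluded from both via ``exclude_positions``.
    """
    if not reads:
        raise ValueError("allele_profile requires at least one read")
    amplicons = {r.amplicon_id for r in reads}
    if len(amplicons) > 1:
        raise ValueError(f"reads span multiple amplicons: {sorted(amplicons)}")
    m: Counter[int] = Counter()
    u: Counter[int] = Counter()
    positions: set[int] = set()
    for read in reads:
        for pos, call in read.cpg_calls.items():
            if pos in exclude_positions:
                continue
            positions.add(pos)
            if call == "M":
                m[pos] += 1
            elif call == "U":
                u[pos] += 1
    per_cpg: dict[int, float | None] = {}
    for pos in sorted(positions):
        tot = m[pos] + u[pos]
        per_cpg[pos] = m[pos] / tot if tot else None
    fracs = [
        f
        for read in reads
        if (f := read_meth_fraction(read, exclude_positions)) is not None
    ]
    mean_frac = fmean(fracs) if fracs else None
    return AlleleProfile(
        allele=allele, n_reads=len(reads), per_cpg_frac=per_cpg, mean_frac=mean_frac
    )


def net_methylation(
    reads: list[BisRead],
    th: Thresholds,
    exclude_positions: frozenset[int] | set[int] = frozenset(),
) -> float | None:
    """Pooled (both alleles) mean per-read methylated fraction for a sample.

    Returns None (no call) below ``net_meth_min_reads`` reads.
    """
    if len(reads) < th.net_meth_min_reads:
        return None
    fracs = [
        f
        for read in reads
        if (f := read_meth_fraction(read, exclude_positions)) is not None
    ]
    if not fracs:
        return None
    return fmean(fracs)
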