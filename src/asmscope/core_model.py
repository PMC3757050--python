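"""Shared domain types, coordinate conventions and the threshold registry.

Coordinates are half-open and 0-based internally, i.e. an interval covers
positions ``start .. end - 1`` and its length is ``end - start``.  Printed
genome-browser coordinate pairs from the source locus tables are imported
verbatim as ``(start, end)`` — their printed spans equal the raw difference
of the endpoints, so no ±1 adjustment is applied on import.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

__all__ = [
    "GenomicInterval",
    "SnpVariant",
    "CpgSite",
    "Thresholds",
    "interval_length",
    "overlaps",
    "window_around",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"start > end in interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def distance_to(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between two intervals; 0 if they touch or overlap,
        None if on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        return max(self.start - other.end, other.start - self.end, 0)


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a half-open interval (``end - start``)."""
    return iv.length


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share a chromosome and intersect.

    Abutting intervals (``a.end == b.start``) do not overlap, following
    standard BED semantics.
    """
    return a.overlaps(b)


def window_around(chrom: str, center_pos: int, width_bp: int) -> GenomicInterval:
    """Half-open window of ``width_bp`` centred on ``center_pos``.

    A window that would extend below coordinate 0 is clamped to 0 with a
    warning (its length is then smaller than ``width_bp``).
    """
    if width_bp <= 0:
        raise ValueError("width_bp must be positive")
    half = width_bp // 2
    start = center_pos - half
    end = center_pos + (width_bp - half)
    if start < 0:
        warnings.warn(
            f"window around {chrom}:{center_pos} clamped at chromosome start",
            stacklevel=2,
        )
        start = 0
    return GenomicInterval(chrom, start, end)


@dataclass(frozen=True)
class SnpVariant:
    """A biallelic SNP with its population heterozygote frequency."""

    id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    het_freq: float = 0.5

    def __post_init__(self) -> None:
        if self.allele_a not in _BASES or self.allele_b not in _BASES:
            raise ValueError(
                f"SNP {self.id}: alleles must be single bases, got "
                f"{self.allele_a!r}/{self.allele_b!r}"
            )
        if self.allele_a == self.allele_b:
            raise ValueError(f"SNP {self.id}: alleles must differ")
        if not 0.0 <= self.het_freq <= 1.0:
            raise ValueError(f"SNP {self.id}: het_freq outside [0,1]")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)


@dataclass(frozen=True)
class CpgSite:
    """The C of one CpG dinucleotide.

    ``is_polymorphic`` marks CpGs destroyed/created by a SNP; apparent ASM at
    such sites is sequence-driven, so they are excluded from methylation
    fractions and (by default) from enrichment analyses.
    """

    chrom: str
    pos: int
    is_polymorphic: bool = False

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("CpG position must be non-negative")


@dataclass(frozen=True)
class Thresholds:
    """Registry of every numeric cutoff used across the pipeline.

    Defaults are the values used throughout the analysis: a 0.30 minimum
    allelic methylation difference for calling ASM, p<0.05 per-sample
    t-tests restricted to samples with ≥5 reads per allele, genotyping at
    ≥10 reads with ≥20% minor-allele reads, net methylation at ≥7 reads,
    >90% / <10% read-methylation bounds for the fully/un-methylated CpG
    classes, 500 bp CpG-centred and 1 kb peak-centred CTCF windows, ±1 kb
    promoter flanks, 250 bp CGI proximity, 100 kb gene association range,
    ≥2 ASM CpGs per qualifying CTCF site, recurrence in ≥2 samples for the
    MSNP screen, and a 1e-6 GWAS p-value ceiling.
    """

    asm_delta_min: float = 0.30
    asm_alpha: float = 0.05
    genotype_min_reads: int = 10
    genotype_minor_frac: float = 0.20
    net_meth_min_reads: int = 7
    asm_min_reads_per_allele: int = 5
    cpg_full_min: float = 0.90
    cpg_unmeth_max: float = 0.10
    ctcf_window_bp: int = 500
    asm_ctcf_window_bp: int = 1000
    promoter_flank_bp: int = 1000
    cgi_proximity_bp: int = 250
    gene_distance_bp: int = 100_000
    asm_cpgs_per_site_min: int = 2
    recurrence_min_samples: int = 2
    gwas_p_max: float = 1e-6
    # config-exposed classifier cutoffs (not printed in the source tables)
    imprint_min_trios: int = 3
    haplotype_concordance_min: float = 0.90

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v <= 0:
                raise ValueError(f"threshold {f.name} must be positive, got {v}")
        for name in (
            "asm_delta_min",
            "asm_alpha",
            "genotype_minor_frac",
            "cpg_full_min",
            "cpg_unmeth_max",
            "gwas_p_max",
            "haplotype_concordance_min",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"threshold {name} must lie in (0,1), got {v}")
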