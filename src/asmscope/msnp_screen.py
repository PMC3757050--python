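"""MSNP screen: candidate ASM loci from methylation-sensitive SNP arrays.

Genomic DNA is pre-digested with HpaII (blocked by CpG methylation) or its
methylation-insensitive isoschizomer MspI before SNP-array probe
synthesis.  At a locus with strong ASM, a heterozygous (AB) call in the
undigested preparation converts to an apparently homozygous call (AA or
BB) after HpaII digestion, because the unmethylated allele's fragment is
cut and drops out.  This module works at the genotype-call level; array
intensity processing is upstream of its input contract.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_model import Thresholds

__all__ = ["DigestCallSet", "CandidateCall", "detect_call_conversion", "recurrent_candidates"]

DIGESTS = ("undigested", "mspI", "hpaII")
CALLS = ("AA", "AB", "BB", "NoCall")


@dataclass(frozen=True)
class DigestCallSet:
    """Genotype calls for one sample under each digest preparation."""

    sample_id: str
    calls: dict[str, dict[str, str]]  # snp_id -> digest -> call

    def complete(self, snp_id: str) -> bool:
        snp = self.calls.get(snp_id, {})
        return all(d in snp for d in DIGESTS)


@dataclass(frozen=True)
class CandidateCall:
    """Per-sample call-conversion verdict at one SNP."""

    snp_id: str
    sample_id: str
    candidate: bool
    mspI_support: bool = False  # MspI NoCall: fragment demonstrably cut
    mspI_caution: bool = False  # MspI still AB: cut sites may be absent
    evaluable: bool = True


def detect_call_conversion(calls: DigestCallSet, snp_id: str) -> CandidateCall:
    """Flag an AB → AA/BB call conversion under HpaII pre-digestion.

    A candidate requires a heterozygous undigested call converting to a
    homozygous call with HpaII.  The MspI call is recorded as supporting
    evidence when it is NoCall (the fragment contains cut sites and drops
    out regardless of methylation) and as a caution when it remains AB.
    Samples lacking any digest call, or with NoCall undigested, are not
    evaluable.
    """
    if not calls.complete(snp_id):
        return CandidateCall(snp_id, calls.sample_id, False, evaluable=False)
    snp = calls.calls[snp_id]
    undigested, mspI, hpaII = (snp[d] for d in DIGESTS)
    if undigested == "NoCall":
        return CandidateCall(snp_id, calls.sample_id, False, evaluable=False)
    candidate = undigested == "AB" and hpaII in ("AA", "BB")
    return CandidateCall(
        snp_id,
        calls.sample_id,
        candidate,
        mspI_support=candidate and mspI == "NoCall",
        mspI_caution=candidate and mspI == "AB",
    )


def recurrent_candidates(
    all_samples: list[DigestCallSet], th: Thresholds
) -> list[str]:
    """SNPs with call conversions in ≥ ``recurrence_min_samples`` samples."""
    counts: dict[str, int] = {}
    for sample in all_samples:
        for snp_id in sample.calls:
            if detect_call_conversion(sample, snp_id).candidate:
                counts[snp_id] = counts.get(snp_id, 0) + 1
    return sorted(s for s, n in counts.items() if n >= th.recurrence_min_samples)
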