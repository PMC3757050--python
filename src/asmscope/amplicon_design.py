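"""Bisulfite-PCR amplicon design against an in-silico converted genome.

Primer panels are designed on both strands of a bisulfite-converted,
SNP-masked template: every non-CpG C converts to T, each CpG C becomes
the ambiguity code Y (its post-conversion base depends on methylation),
and positions of SNPs above a 1% heterozygote frequency are masked to N.
Candidate primers must avoid masked bases, carry at most one CpG (zero
preferred), and fall inside the Tm and GC windows; pairs must yield a
product in the allowed size band, form no self/cross/hairpin duplex with
a predicted melting temperature above the structure ceiling, and produce
no off-target product of 50–2000 bp anywhere in the converted genome
when up to two mismatches per primer (3'-terminal base anchored) are
allowed — the same screen NCBI reverse e-PCR applies.  Selected amplicons
must bracket at least four CpGs and one SNP with heterozygosity ≥ 0.2.

The melting-temperature model is nearest-neighbor thermodynamics at
50 mM monovalent salt and 250 nM primer; CpG Y codes are evaluated as T
(the unmethylated, fully converted template).  Secondary structure is
approximated by the maximal-complementarity duplex between the two
sequences (full folding is out of scope).  The pipeline is deterministic:
re-running on the same inputs is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from Bio.SeqUtils import MeltingTemp, gc_fraction

from .core_model import GenomicInterval, SnpVariant

__all__ = [
    "DesignConstraints",
    "PrimerPair",
    "ConvertedTemplate",
    "convert_and_mask",
    "enumerate_primer_pairs",
    "offtarget_scan",
    "select_amplicons",
    "design_panel",
]

_COMPLEMENT = str.maketrans("ACGTYRN", "TGCARYN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DesignConstraints:
    """The full printed constraint set for bisulfite primer design."""

    tm_range: tuple[float, float] = (56.0, 60.0)
    gc_range: tuple[float, float] = (0.35, 0.65)
    max_cpgs_per_primer: int = 1
    amplicon_size: tuple[int, int] = (200, 650)
    preferred_size: tuple[int, int] = (200, 450)
    structure_tm_max: float = 46.0
    offtarget_size: tuple[int, int] = (50, 2000)
    offtarget_mismatches: int = 2
    min_amplicon_cpgs: int = 4
    min_snp_het: float = 0.2
    snp_mask_het_freq: float = 0.01
    primer_len_range: tuple[int, int] = (18, 27)
    # nearest-neighbor Tm model conditions (config-exposed)
    salt_mM: float = 50.0
    primer_nM: float = 250.0

    def __post_init__(self) -> None:
        for name in ("tm_range", "gc_range", "amplicon_size", "preferred_size",
                     "offtarget_size", "primer_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is an empty range")


@dataclass(frozen=True)
class ConvertedTemplate:
    """One strand of the converted, masked genome.

    ``strand`` is "top" or "bottom"; the sequence is written 5'→3' in the
    strand's own orientation, so bottom-template index i maps to genome
    position ``len - 1 - i``.
    """

    chrom: str
    strand: str
    seq: str

    def to_genome(self, start: int, end: int) -> tuple[int, int]:
        """Map a half-open template slice to genome coordinates."""
        if self.strand == "top":
            return start, end
        n = len(self.seq)
        return n - end, n - start


@dataclass(frozen=True)
class PrimerPair:
    """An accepted primer pair with its product and per-primer metrics."""

    forward: str
    reverse: str
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    cpgs_forward: int
    cpgs_reverse: int
    chrom: str
    strand: str
    product: GenomicInterval  # genome coordinates
    template_start: int  # template coordinates of the product
    template_end: int
    n_cpgs_covered: int = 0

    @property
    def size(self) -> int:
        return self.product.length


def convert_and_mask(
    genome: dict[str, str],
    snps: list[SnpVariant],
    c: DesignConstraints = DesignConstraints(),
) -> dict[str, dict[str, ConvertedTemplate]]:
    """In-silico bisulfite conversion of both strands with SNP masking.

    Returns ``{chrom: {"top": ..., "bottom": ...}}``.  Non-ACGTN input is
    an error naming the position.
    """
    mask: dict[str, set[int]] = {}
    for snp in snps:
        if snp.het_freq > c.snp_mask_het_freq:
            mask.setdefault(snp.chrom, set()).add(snp.pos)
    out: dict[str, dict[str, ConvertedTemplate]] = {}
    for chrom, seq in genome.items():
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            pos = next(i for i, ch in enumerate(seq) if ch in bad)
            raise ValueError(f"{chrom}: invalid character {seq[pos]!r} at position {pos}")
        positions = mask.get(chrom, set())
        masked = "".join("N" if i in positions else ch for i, ch in enumerate(seq))
        out[chrom] = {
            "top": ConvertedTemplate(chrom, "top", _convert_strand(masked)),
            "bottom": ConvertedTemplate(
                chrom, "bottom", _convert_strand(_revcomp(masked))
            ),
        }
    return out


def _convert_strand(seq: str) -> str:
    """C→T except CpG C→Y (methylation-dependent); N propagates."""
    out = list(seq)
    for i, ch in enumerate(seq):
        if ch != "C":
            continue
        if i + 1 < len(seq) and seq[i + 1] == "G":
            out[i] = "Y"
        else:
            out[i] = "T"
    return "".join(out)


def _as_unmethylated(seq: str) -> str:
    """Resolve ambiguity codes to the fully converted (unmethylated) base."""
    return seq.replace("Y", "T").replace("R", "A")


def _primer_tm(seq: str, c: DesignConstraints) -> float:
    return float(
        MeltingTemp.Tm_NN(
            _as_unmethylated(seq), Na=c.salt_mM, dnac1=c.primer_nM, dnac2=0.0
        )
    )


def _duplex_tm(s1: str, s2: str, c: DesignConstraints) -> float:
    """Melting temperature of the maximal-complementarity duplex between
    two primers (longest contiguous Watson-Crick stretch when s1 anneals
    antiparallel to s2); the proxy used for dimer/hairpin screening."""
    a = _as_unmethylated(s1)
    b = _revcomp(_as_unmethylated(s2))
    # longest common substring of a and b
    best = ""
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > len(best):
                    best = a[i - cur[j] : i]
        prev = cur
    if len(best) < 4:
        return -273.15  # too short to form a stable duplex
    return float(
        MeltingTemp.Tm_NN(best, Na=c.salt_mM, dnac1=c.primer_nM, dnac2=0.0)
    )


@dataclass
class _Candidate:
    start: int  # template coordinate
    length: int
    seq: str  # template-orientation sequence (may contain Y)
    tm: float
    gc: float
    cpgs: int


def _enumerate_single_primers(
    template: str, lo: int, hi: int, c: DesignConstraints, reverse: bool
) -> list[_Candidate]:
    """All single primers binding in template slice [lo, hi) that pass the
    per-primer constraints.  For reverse=True the primer sequence is the
    reverse complement of the template slice."""
    out = []
    pmin, pmax = c.primer_len_range
    for start in range(lo, hi):
        for length in range(pmin, pmax + 1):
            if start + length > hi:
                break
            sub = template[start : start + length]
            if "N" in sub:
                continue
            cpgs = sub.count("Y")
            if cpgs > c.max_cpgs_per_primer:
                continue
            seq = _revcomp(sub) if reverse else sub
            gc = gc_fraction(_as_unmethylated(seq))
            if not c.gc_range[0] <= gc <= c.gc_range[1]:
                continue
            tm = _primer_tm(seq, c)
            if not c.tm_range[0] <= tm <= c.tm_range[1]:
                continue
            out.append(_Candidate(start, length, seq, tm, gc, cpgs))
    return out


def enumerate_primer_pairs(
    template: ConvertedTemplate,
    region: tuple[int, int],
    c: DesignConstraints = DesignConstraints(),
    must_span: tuple[int, int] | None = None,
) -> list[PrimerPair]:
    """All primer pairs within a template region passing the per-primer
    and pair constraints (Tm, GC, CpG count, product size, structure);
    the off-target screen is a separate step.  Pairs overlapping masked N
    bases are rejected.  ``must_span`` (template coordinates) restricts
    pairs to those whose inter-primer region contains the given core —
    the CpG/SNP payload the amplicon exists to read out.  Returns pairs
    in deterministic template order.
    """
    lo, hi = region
    if hi - lo < c.amplicon_size[0]:
        return []
    fwd_hi, rev_lo = hi, lo
    if must_span is not None:
        fwd_hi, rev_lo = must_span
        fwd_hi = max(lo, min(fwd_hi, hi))
        rev_lo = max(lo, min(rev_lo, hi))
    fwd = _enumerate_single_primers(template.seq, lo, fwd_hi, c, reverse=False)
    rev = _enumerate_single_primers(template.seq, rev_lo, hi, c, reverse=True)
    duplex_cache: dict[tuple[str, str], float] = {}

    def duplex(s1: str, s2: str) -> float:
        key = (s1, s2)
        if key not in duplex_cache:
            duplex_cache[key] = _duplex_tm(s1, s2, c)
        return duplex_cache[key]

    fwd = [f for f in fwd if duplex(f.seq, f.seq) <= c.structure_tm_max]
    rev = [r for r in rev if duplex(r.seq, r.seq) <= c.structure_tm_max]
    pairs = []
    for f in fwd:
        for r in rev:
            start, end = f.start, r.start + r.length
            size = end - start
            if size < c.amplicon_size[0] or size > c.amplicon_size[1]:
                continue
            if r.start <= f.start + f.length:  # primers must not overlap
                continue
            if duplex(f.seq, r.seq) > c.structure_tm_max:
                continue
            gstart, gend = template.to_genome(start, end)
            pairs.append(
                PrimerPair(
                    forward=f.seq,
                    reverse=r.seq,
                    tm_forward=f.tm,
                    tm_reverse=r.tm,
                    gc_forward=f.gc,
                    gc_reverse=r.gc,
                    cpgs_forward=f.cpgs,
                    cpgs_reverse=r.cpgs,
                    chrom=template.chrom,
                    strand=template.strand,
                    product=GenomicInterval(template.chrom, gstart, gend),
                    template_start=start,
                    template_end=end,
                )
            )
    pairs.sort(key=lambda p: (p.template_start, p.template_end, p.forward, p.reverse))
    return pairs


# --- off-target scan (reverse e-PCR style) ---------------------------------

_CODE = {ch: i for i, ch in enumerate("ACGTYRN")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _match_matrix() -> np.ndarray:
    """match[t_byte, p_byte]: does template char t pair with primer char p?
    Y (converted CpG C) matches primer C or T; N matches nothing."""
    m = np.zeros((256, 256), dtype=bool)
    for t in "ACGT":
        m[ord(t), ord(t)] = True
    m[ord("Y"), ord("C")] = True
    m[ord("Y"), ord("T")] = True
    return m


_MATCH = _match_matrix()


def _binding_sites(
    primer: str, template_arr: np.ndarray, c: DesignConstraints
) -> tuple[np.ndarray, np.ndarray]:
    """Start positions where the primer binds the template.

    Returns (rightward, leftward): rightward sites are where the primer
    matches the template sense (extension to the right; 3' base is the
    last position); leftward sites are where the primer's reverse
    complement matches (extension to the left; 3' base is the first
    position of the match).  ≤ ``offtarget_mismatches`` mismatches with
    an exact 3'-terminal base are required.
    """
    L = len(template_arr)

    def scan(pat: str, three_prime_last: bool) -> np.ndarray:
        parr = _encode(pat)
        k = len(parr)
        if L < k:
            return np.empty(0, dtype=int)
        n = L - k + 1
        mism = np.zeros(n, dtype=np.int16)
        for j in range(k):
            mism += ~_MATCH[template_arr[j : j + n], parr[j]]
        ok = mism <= c.offtarget_mismatches
        anchor_j = k - 1 if three_prime_last else 0
        ok &= _MATCH[template_arr[anchor_j : anchor_j + n], parr[anchor_j]]
        return np.nonzero(ok)[0]

    rightward = scan(primer, three_prime_last=True)
    leftward = scan(_revcomp(primer), three_prime_last=False)
    return rightward, leftward


def offtarget_scan(
    pair: PrimerPair,
    templates: dict[str, dict[str, ConvertedTemplate]],
    c: DesignConstraints = DesignConstraints(),
    _cache: dict | None = None,
) -> tuple[bool, list[tuple[str, str, int, int]]]:
    """Screen a pair against every converted template strand.

    Any primer-pair binding-site combination (either primer in either
    orientation) producing a product of ``offtarget_size`` other than the
    intended target fails the pair.  Returns (passes, hits) with hits as
    (chrom, strand, start, end) template coordinates.
    """
    size_lo, size_hi = c.offtarget_size
    hits: list[tuple[str, str, int, int]] = []
    primers = (pair.forward, pair.reverse)
    for chrom, strands in templates.items():
        for strand, template in strands.items():
            arr = _encode(template.seq)
            sites_right: list[np.ndarray] = []
            sites_left_end: list[np.ndarray] = []
            for p in primers:
                key = (p, chrom, strand)
                if _cache is not None and key in _cache:
                    right, left = _cache[key]
                else:
                    right, left = _binding_sites(p, arr, c)
                    if _cache is not None:
                        _cache[key] = (right, left)
                sites_right.append(right)
                sites_left_end.append(left + len(p))  # product right edge
            target = None
            if chrom == pair.chrom and strand == pair.strand:
                target = (pair.template_start, pair.template_end)
            for right in sites_right:
                for left_end in sites_left_end:
                    for s in right:
                        # products with this rightward site
                        cand = left_end[(left_end >= s + size_lo) & (left_end <= s + size_hi)]
                        for e in cand:
                            if target is not None and (int(s), int(e)) == target:
                                continue
                            hits.append((chrom, strand, int(s), int(e)))
    return len(hits) == 0, hits


def select_amplicons(
    candidates: list[PrimerPair],
    snps: list[SnpVariant],
    cpg_positions: dict[str, list[int]],
    c: DesignConstraints = DesignConstraints(),
) -> list[PrimerPair]:
    """Filter and rank off-target-clean pairs into an amplicon panel.

    Keeps pairs whose inter-primer region covers ≥ ``min_amplicon_cpgs``
    CpGs and ≥1 SNP with heterozygosity ≥ ``min_snp_het``; ranks by fewer
    primer CpGs, then size inside the preferred band, then more CpGs
    covered.  Issues a warning naming the binding constraint when nothing
    survives.
    """
    import warnings

    kept = []
    for pair in candidates:
        inner_start = pair.product.start + len(pair.forward)
        inner_end = pair.product.end - len(pair.reverse)
        cpgs_in = [
            p
            for p in cpg_positions.get(pair.chrom, [])
            if inner_start <= p < inner_end
        ]
        if len(cpgs_in) < c.min_amplicon_cpgs:
            continue
        snps_in = [
            s
            for s in snps
            if s.chrom == pair.chrom
            and inner_start <= s.pos < inner_end
            and s.het_freq >= c.min_snp_het
        ]
        if not snps_in:
            continue
        kept.append(replace(pair, n_cpgs_covered=len(cpgs_in)))
    if not kept:
        warnings.warn(
            "no amplicon passed selection: check CpG coverage "
            f"(≥{c.min_amplicon_cpgs}) and SNP heterozygosity (≥{c.min_snp_het})",
            stacklevel=2,
        )
    lo, hi = c.preferred_size
    kept.sort(
        key=lambda p: (
            p.cpgs_forward + p.cpgs_reverse,
            0 if lo <= p.size <= hi else 1,
            -p.n_cpgs_covered,
            p.product.start,
            p.size,
            p.forward,
        )
    )
    return kept


def design_panel(
    genome: dict[str, str],
    snps: list[SnpVariant],
    cpg_positions: dict[str, list[int]],
    regions: list[GenomicInterval],
    c: DesignConstraints = DesignConstraints(),
    max_pairs_per_region: int = 1,
) -> list[PrimerPair]:
    """End-to-end design: convert and mask, enumerate pairs on both
    strands of each target region, screen off-targets genome-wide, select
    and rank, and return up to ``max_pairs_per_region`` non-overlapping
    winners per region.  Deterministic for fixed inputs."""
    templates = convert_and_mask(genome, snps, c)
    cache: dict = {}
    panel: list[PrimerPair] = []
    for region in regions:
        strands = templates[region.chrom]
        candidates: list[PrimerPair] = []
        n = len(genome[region.chrom])
        # the payload the amplicon must bracket: CpGs and assayable SNPs
        core = [
            p
            for p in cpg_positions.get(region.chrom, [])
            if region.start <= p < region.end
        ] + [
            s.pos
            for s in snps
            if s.chrom == region.chrom
            and region.start <= s.pos < region.end
            and s.het_freq >= c.min_snp_het
        ]
        gspan = (min(core), max(core) + 1) if core else None
        for strand, template in sorted(strands.items()):
            if strand == "top":
                tregion = (region.start, region.end)
                tspan = gspan
            else:
                tregion = (n - region.end, n - region.start)
                tspan = (n - gspan[1], n - gspan[0]) if gspan else None
            candidates.extend(
                enumerate_primer_pairs(template, tregion, c, must_span=tspan)
            )
        ranked = select_amplicons(candidates, snps, cpg_positions, c)
        chosen: list[PrimerPair] = []
        for pair in ranked:
            if len(chosen) >= max_pairs_per_region:
                break
            if any(pair.product.overlaps(q.product) for q in chosen):
                continue
            ok, _ = offtarget_scan(pair, templates, c, _cache=cache)
            if ok:
                chosen.append(pair)
        panel.extend(chosen)
    return panel
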