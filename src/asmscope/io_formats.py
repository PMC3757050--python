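"""Readers/writers for the pipeline's tabular dialects and BED-like tracks.

Reads are modeled post-alignment and post-basecall: the unit of input is a
TSV of phased calls, one row per bisulfite read, not FASTQ/SAM.  Column
order is fixed and documented per dialect below.

Read-table dialect (TSV, header required)::

    sample_id  tissue  individual_id  amplicon_id  snp_calls  cpg_calls

``snp_calls``  — ``snp_id=BASE`` entries joined by ``;`` (e.g. ``rs1=A``)
``cpg_calls``  — ``pos=CODE`` entries joined by ``;`` with code M, U or "."
                 (missing), e.g. ``1000=M;1007=U;1015=.``

Feature tracks are BED3 (ctcf, cgi, block), BED6 for genes (TSS taken from
the strand-appropriate end) and a 5-column TSV for GWAS SNPs
(``snp  chrom  pos  trait  p``).  Chromosome names pass through verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .allele_methylation import MISSING, METH_CODES, BisRead
from .asm_stats import AsmCallMatrix, TissueCell
from .core_model import GenomicInterval, Thresholds

__all__ = [
    "ReadTable",
    "AmpliconDef",
    "GeneRecord",
    "GwasSnp",
    "RunConfig",
    "ReadTableError",
    "load_read_table",
    "write_read_table",
    "load_feature_track",
    "write_heatmap_table",
    "load_heatmap_table",
    "load_run_config",
]

logger = logging.getLogger(__name__)

READ_TABLE_COLUMNS = (
    "sample_id",
    "tissue",
    "individual_id",
    "amplicon_id",
    "snp_calls",
    "cpg_calls",
)

TRACK_KINDS = ("ctcf", "cgi", "gene", "block", "gwas_snp")


class ReadTableError(ValueError):
    """Malformed read-table input; message names the offending row."""


@dataclass(frozen=True)
class AmpliconDef:
    """Declared layout of one bisulfite amplicon."""

    amplicon_id: str
    interval: GenomicInterval
    cpg_positions: tuple[int, ...]
    snp_id: str = ""


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval with its transcription start site."""

    name: str
    interval: GenomicInterval
    strand: str
    tss: int


@dataclass(frozen=True)
class GwasSnp:
    snp: str
    chrom: str
    pos: int
    trait: str
    p: float


@dataclass
class ReadTable:
    """A validated collection of phased bisulfite reads."""

    reads: list[BisRead]
    amplicons: dict[str, AmpliconDef] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for read in self.reads:
            amp = self.amplicons.get(read.amplicon_id)
            if amp is None:
                continue
            declared = set(amp.cpg_positions)
            extra = set(read.cpg_calls) - declared
            if extra:
                raise ReadTableError(
                    f"read in sample {read.sample_id}: CpG position(s) "
                    f"{sorted(extra)} not declared for amplicon {read.amplicon_id}"
                )

    def __len__(self) -> int:
        return len(self.reads)

    def by_sample(self) -> dict[tuple[str, str, str], list[BisRead]]:
        """Group reads as (amplicon_id, tissue, sample_id) -> reads."""
        grouped: dict[tuple[str, str, str], list[BisRead]] = {}
        for read in self.reads:
            key = (read.amplicon_id, read.tissue, read.sample_id)
            grouped.setdefault(key, []).append(read)
        return grouped


def _parse_snp_calls(text: str, row: int) -> dict[str, str]:
    calls: dict[str, str] = {}
    if not text or text == ".":
        return calls
    for item in text.split(";"):
        if "=" not in item:
            raise ReadTableError(f"row {row}: malformed snp_calls entry {item!r}")
        snp_id, base = item.split("=", 1)
        calls[snp_id] = base
    return calls


def _parse_cpg_calls(text: str, row: int) -> dict[int, str]:
    calls: dict[int, str] = {}
    for item in text.split(";"):
        if "=" not in item:
            raise ReadTableError(f"row {row}: malformed cpg_calls entry {item!r}")
        pos_s, code = item.split("=", 1)
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise ReadTableError(f"row {row}: non-integer CpG position {pos_s!r}") from exc
        if code not in METH_CODES:
            raise ReadTableError(
                f"row {row}: unknown methylation code {code!r} at position {pos}"
            )
        calls[pos] = code
    return calls


def load_read_table(
    path: str | Path, amplicons: dict[str, AmpliconDef] | None = None
) -> ReadTable:
    """Load and validate a phased read table.

    Missing columns and unknown methylation codes are hard errors naming
    the row; an empty file with a valid header yields an empty table with
    a warning in the log.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != READ_TABLE_COLUMNS:
            missing = set(READ_TABLE_COLUMNS) - set(header)
            raise ReadTableError(
                f"{path}: bad header; missing column(s) {sorted(missing)}"
                if missing
                else f"{path}: header column order must be {READ_TABLE_COLUMNS}"
            )
        reads: list[BisRead] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(READ_TABLE_COLUMNS):
                raise ReadTableError(
                    f"row {lineno}: expected {len(READ_TABLE_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            sample_id, tissue, individual_id, amplicon_id, snp_s, cpg_s = parts
            reads.append(
                BisRead(
                    sample_id=sample_id,
                    tissue=tissue,
                    individual_id=individual_id,
                    amplicon_id=amplicon_id,
                    snp_calls=_parse_snp_calls(snp_s, lineno),
                    cpg_calls=_parse_cpg_calls(cpg_s, lineno),
                )
            )
    if not reads:
        logger.warning("%s: read table is empty", path)
    return ReadTable(reads=reads, amplicons=amplicons or {})


def write_read_table(table: ReadTable, path: str | Path) -> None:
    """Write a read table in the documented TSV dialect (round-trips)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(READ_TABLE_COLUMNS) + "\n")
        for r in table.reads:
            snp_s = ";".join(f"{k}={v}" for k, v in sorted(r.snp_calls.items())) or "."
            cpg_s = ";".join(f"{p}={c}" for p, c in sorted(r.cpg_calls.items()))
            fh.write(
                "\t".join(
                    (r.sample_id, r.tissue, r.individual_id, r.amplicon_id, snp_s, cpg_s)
                )
                + "\n"
            )


def load_feature_track(path: str | Path, kind: str, th: Thresholds | None = None):
    """Load a genomic feature track.

    kind ``ctcf``/``cgi``/``block``: BED3 → sorted list of GenomicInterval.
    kind ``gene``: BED6 → list of GeneRecord with TSS at the 5' end per
    strand.  kind ``gwas_snp``: TSV (snp, chrom, pos, trait, p) filtered to
    p ≤ ``gwas_p_max``.  Unsorted input is accepted and sorted; negative
    coordinates are an error.
    """
    if kind not in TRACK_KINDS:
        raise ValueError(f"unknown track kind {kind!r}; expected one of {TRACK_KINDS}")
    path = Path(path)
    rows = [
        line.rstrip("\n").split("\t")
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith(("#", "track", "browser"))
    ]
    if kind == "gwas_snp":
        th = th or Thresholds()
        out: list[GwasSnp] = []
        for parts in rows:
            if parts[0] == "snp":  # optional header
                continue
            snp, chrom, pos_s, trait, p_s = parts[:5]
            rec = GwasSnp(snp, chrom, int(pos_s), trait, float(p_s))
            if rec.pos < 0:
                raise ValueError(f"{path}: negative coordinate for {snp}")
            if rec.p <= th.gwas_p_max:
                out.append(rec)
            else:
                logger.info("GWAS SNP %s dropped (p=%g above ceiling)", snp, rec.p)
        return sorted(out, key=lambda r: (r.chrom, r.pos))
    if kind == "gene":
        genes = []
        for parts in rows:
            chrom, start_s, end_s, name = parts[:4]
            strand = parts[5] if len(parts) > 5 else "+"
            start, end = int(start_s), int(end_s)
            if start < 0:
                raise ValueError(f"{path}: negative coordinate in gene {name}")
            iv = GenomicInterval(chrom, start, end)
            tss = iv.start if strand == "+" else iv.end
            genes.append(GeneRecord(name=name, interval=iv, strand=strand, tss=tss))
        return sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start))
    intervals = []
    for parts in rows:
        chrom, start_s, end_s = parts[:3]
        start, end = int(start_s), int(end_s)
        if start < 0:
            raise ValueError(f"{path}: negative coordinate on {chrom}")
        intervals.append(GenomicInterval(chrom, start, end))
    return sorted(intervals)


def write_heatmap_table(matrix: AsmCallMatrix, path: str | Path) -> None:
    """Serialize an ASM heat map as TSV; cells are ``category:delta``.

    Δ is the cell's mean |Δ| methylation written with 2 decimals, or ``NA``
    for category-only cells.  The amplicon coordinate columns make the file
    round-trip losslessly through :func:`load_heatmap_table`.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "\t".join(["amplicon_id", "chrom", "start", "end"] + list(matrix.tissues))
            + "\n"
        )
        for amp_id, iv in matrix.amplicons:
            row = [amp_id, iv.chrom, str(iv.start), str(iv.end)]
            for tissue in matrix.tissues:
                cell = matrix.cells[(amp_id, tissue)]
                delta = "NA" if cell.mean_abs_delta is None else f"{cell.mean_abs_delta:.2f}"
                frac = "NA" if cell.frac_significant is None else f"{cell.frac_significant:.4f}"
                row.append(f"{cell.category}:{delta}:{frac}:{cell.n_het}")
            fh.write("\t".join(row) + "\n")


def load_heatmap_table(path: str | Path) -> AsmCallMatrix:
    """Read back a heat-map TSV written by :func:`write_heatmap_table`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")
    tissues = header[4:]
    amplicons: list[tuple[str, GenomicInterval]] = []
    cells: dict[tuple[str, str], TissueCell] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        amp_id, chrom, start_s, end_s = parts[:4]
        amplicons.append((amp_id, GenomicInterval(chrom, int(start_s), int(end_s))))
        for tissue, cell_s in zip(tissues, parts[4:]):
            category, delta_s, frac_s, n_het_s = cell_s.split(":")
            cells[(amp_id, tissue)] = TissueCell(
                amplicon_id=amp_id,
                tissue=tissue,
                n_het=int(n_het_s),
                mean_abs_delta=None if delta_s == "NA" else float(delta_s),
                frac_significant=None if frac_s == "NA" else float(frac_s),
                category=category,
            )
    return AsmCallMatrix(amplicons=amplicons, tissues=tissues, cells=cells)


@dataclass
class RunConfig:
    """Run configuration: thresholds, seed, input paths, tissue list.

    The seed is recorded here so every output a run writes can cite it.
    """

    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)
    tissues: list[str] = field(default_factory=list)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown threshold keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    th = Thresholds(**raw.get("thresholds", {}))
    return RunConfig(
        thresholds=th,
        seed=int(raw.get("seed", 0)),
        paths=dict(raw.get("paths", {})),
        tissues=list(raw.get("tissues", [])),
    )
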