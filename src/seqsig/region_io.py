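"""Genomic region I/O and TSS window extraction.

Windows are strand-oriented 2,004-bp regions centred on a transcription
start site and tiled into 334 non-overlapping 6-bp segments.  All
coordinates are 0-based half-open internally; BED is read natively and
GTF is converted at the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("seqsig")

WINDOW_LENGTH = 2004
SEGMENT_LENGTH = 6
N_SEGMENTS = WINDOW_LENGTH // SEGMENT_LENGTH  # 334

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _sanitize(seq: str) -> str:
    """Uppercase and collapse every non-ACGT letter to N."""
    seq = seq.upper()
    if set(seq) <= _VALID_BASES:
        return seq
    return "".join(b if b in _VALID_BASES else "N" for b in seq)


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored at its TSS.  `body` is an optional (start, end) span."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    body: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"negative TSS for gene {self.gene_id}")


@dataclass(frozen=True)
class TssWindow:
    """A 2,004-bp gene-oriented window around a TSS, tiled into 6-bp segments.

    ``segments`` runs 5'→3' relative to the gene: for minus-strand genes the
    genomic forward sequence is reverse-complemented, so segment 1 is always
    the most upstream of the gene.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    start: int
    end: int
    segments: tuple[str, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if self.end - self.start != WINDOW_LENGTH:
            raise ValueError(
                f"window span must be {WINDOW_LENGTH} bp, got {self.end - self.start}"
            )
        if len(self.segments) != N_SEGMENTS:
            raise ValueError(
                f"expected {N_SEGMENTS} segments, got {len(self.segments)}"
            )

    @property
    def sequence(self) -> str:
        """The oriented window sequence (concatenation of the segments)."""
        return "".join(self.segments)

    def segment_span(self, i: int) -> tuple[int, int]:
        """Genomic [start, end) of oriented segment ``i`` (0-based)."""
        if not 0 <= i < N_SEGMENTS:
            raise IndexError(f"segment index {i} out of range")
        if self.strand == "+":
            s = self.start + i * SEGMENT_LENGTH
        else:
            s = self.end - (i + 1) * SEGMENT_LENGTH
        return s, s + SEGMENT_LENGTH


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-record) FASTA into {name: uppercase ACGTN sequence}."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _sanitize(str(rec.seq))
        if not seq:
            raise ValueError(f"empty FASTA record: {rec.id!r}")
        genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def extract_tss_windows(
    genes: Iterable[GeneRecord],
    genome: Mapping[str, str],
    half_width: int = WINDOW_LENGTH // 2,
    orient_minus: bool = True,
) -> list[TssWindow]:
    """Extract gene-oriented windows of ``2*half_width`` bp around each TSS.

    For a plus-strand gene the genomic span is [tss-half_width, tss+half_width);
    for a minus-strand gene it is [tss-half_width+1, tss+half_width+1),
    reverse-complemented (when ``orient_minus``) so the TSS sits at the same
    segment boundary in gene coordinates.  Windows falling off a chromosome
    are skipped with a warning; an unknown chromosome is an error.
    """
    length = 2 * half_width
    if length % SEGMENT_LENGTH != 0:
        raise ValueError("window length must be a multiple of 6")
    out: list[TssWindow] = []
    for g in genes:
        if g.chrom not in genome:
            raise KeyError(f"unknown chromosome {g.chrom!r} for gene {g.gene_id}")
        chrom_seq = genome[g.chrom]
        if g.strand == "+":
            start = g.tss - half_width
        else:
            start = g.tss - half_width + 1
        end = start + length
        if start < 0 or end > len(chrom_seq):
            logger.warning(
                "window for gene %s [%d, %d) falls outside %s; skipped",
                g.gene_id, start, end, g.chrom,
            )
            continue
        seq = chrom_seq[start:end]
        if g.strand == "-" and orient_minus:
            seq = reverse_complement(seq)
        segments = tuple(
            seq[i : i + SEGMENT_LENGTH] for i in range(0, length, SEGMENT_LENGTH)
        )
        out.append(
            TssWindow(
                gene_id=g.gene_id, chrom=g.chrom, tss=g.tss, strand=g.strand,
                start=start, end=end, segments=segments,
            )
        )
    return out


def read_regions(path, format: str = "BED") -> list[GeneRecord]:
    """Read gene records from BED6 (0-based half-open) or GTF (1-based closed).

    TSS is the interval start for plus-strand genes and end-1 for
    minus-strand genes, in 0-based coordinates.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GTF"):
        raise ValueError(f"format must be BED or GTF, got {format!r}")
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    gene_id = fields[3] if len(fields) > 3 else f"region_{lineno}"
                    strand = fields[5] if len(fields) > 5 else "+"
                else:
                    if len(fields) < 8:
                        raise ValueError("fewer than 8 GTF fields")
                    if fields[2] not in ("gene", "transcript"):
                        continue
                    chrom = fields[0]
                    start = int(fields[3]) - 1  # 1-based closed → 0-based half-open
                    end = int(fields[4])
                    strand = fields[6]
                    gene_id = _gtf_attribute(fields[8], "gene_id") if len(fields) > 8 else f"region_{lineno}"
                if end <= start:
                    raise ValueError(f"empty interval [{start}, {end})")
                tss = start if strand == "+" else end - 1
                genes.append(
                    GeneRecord(gene_id=gene_id, chrom=chrom, tss=tss,
                               strand=strand, body=(start, end))
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {fmt} line: {exc}") from exc
    return genes


def _gtf_attribute(attrs: str, key: str) -> str:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key):
            return part[len(key):].strip().strip('"')
    raise ValueError(f"missing {key} attribute")


def write_regions_bed(genes: Iterable[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            body = g.body if g.body is not None else (g.tss, g.tss + 1)
            fh.write(f"{g.chrom}\t{body[0]}\t{body[1]}\t{g.gene_id}\t0\t{g.strand}\n")


class ExpressionTable:
    """Gene-level FPKM with derived log2(FPKM+1) levels and a detected flag.

    Transcripts with FPKM between 0 and 1 are treated as not significantly
    detected, so ``detected`` is the strict fpkm > 1 flag.
    """

    DETECTION_FPKM = 1.0

    def __init__(self, fpkm: Mapping[str, float] | pd.Series):
        s = pd.Series(fpkm, dtype=float)
        if s.index.has_duplicates:
            dups = s.index[s.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if (s < 0).any():
            bad = s.index[s < 0].tolist()
            raise ValueError(f"negative FPKM for genes: {bad}")
        self._df = pd.DataFrame(
            {
                "fpkm": s,
                "log_level": np.log2(s + 1.0),
                "detected": s > self.DETECTION_FPKM,
            }
        )
        self._df.index.name = "gene_id"

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def fpkm(self) -> pd.Series:
        return self._df["fpkm"]

    @property
    def log_level(self) -> pd.Series:
        return self._df["log_level"]

    @property
    def detected(self) -> pd.Series:
        return self._df["detected"]

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._df.index

    def subset(self, gene_ids) -> "ExpressionTable":
        return ExpressionTable(self._df.loc[list(gene_ids), "fpkm"])


def read_expression(path) -> ExpressionTable:
    """Read a TSV of gene_id + one or more FPKM replicate columns.

    Replicate columns are averaged; negative FPKM or duplicated gene ids are
    errors.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected gene_id plus at least one FPKM column")
    gene_col = df.columns[0]
    values = df.iloc[:, 1:]
    if not all(np.issubdtype(dt, np.number) for dt in values.dtypes):
        raise ValueError(f"{path}: non-numeric FPKM column")
    fpkm = values.mean(axis=1)
    fpkm.index = df[gene_col].astype(str)
    return ExpressionTable(fpkm)


def write_expression(table: ExpressionTable, path) -> None:
    table.frame[["fpkm"]].to_csv(path, sep="\t")
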