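"""Readers and writers for the formats the pipeline consumes and emits.

All genomic coordinates in TSV reports are 1-based and fully closed
(SAM/GFF3 convention). The SAM dialect handled here is deliberately
narrow: single-segment reads, FLAG 0 or 16, CIGAR restricted to
M/I/D/S (and the exact =/X forms, treated as M). Anything else is
rejected loudly rather than silently skipped.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SUPPORTED_CIGAR_OPS = frozenset("MIDS=X")
FASTA_WRAP = 60

#: Phred+33 quality character for the constant Q37 emitted by the simulator.
Q37_CHAR = chr(37 + 33)


@dataclasses.dataclass
class GenomeRecord:
    """A genome (or contig) sequence over the unambiguous DNA alphabet."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(
                f"genome {self.id!r}: alphabet restricted to A,C,G,T, found {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class Gene:
    """A protein-coding gene interval, 1-based fully-closed on its genome."""

    gene_id: str
    seqid: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.gene_id!r}: invalid interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class SamRead:
    """One alignment line of the supported SAM subset.

    ``sequence`` is stored as in SAM, i.e. on the forward reference
    strand; for reverse-strand reads (flag 16) the sequenced read is its
    reverse complement.
    """

    qname: str
    flag: int
    rname: str
    pos: int  # 1-based leftmost reference position
    cigar: str
    sequence: str
    mapq: int = 60

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 16)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 4)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(path: str | os.PathLike, genomes: Iterable[GenomeRecord]) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="circular" if g.circular else "")
        for g in genomes
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=FASTA_WRAP)
        writer.write_file(records)


def read_fasta(path: str | os.PathLike) -> list[GenomeRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circular = "circular" in rec.description.split()[1:]
        out.append(GenomeRecord(rec.id, str(rec.seq).upper(), circular=circular))
    return out


def write_fastq(path: str | os.PathLike, reads: Iterable[tuple[str, str]]) -> None:
    """Write (name, sequence) pairs with a constant Q37 quality string."""
    with open(path, "w") as handle:
        for name, seq in reads:
            handle.write(f"@{name}\n{seq}\n+\n{Q37_CHAR * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# SAM subset


def write_sam(
    path: str | os.PathLike,
    references: Sequence[tuple[str, int]],
    reads: Iterable[SamRead],
) -> None:
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in references:
            handle.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in reads:
            handle.write(
                f"{r.qname}\t{r.flag}\t{r.rname}\t{r.pos}\t{r.mapq}\t{r.cigar}"
                f"\t*\t0\t0\t{r.sequence}\t{Q37_CHAR * len(r.sequence)}\n"
            )


def check_cigar(cigar: str, qname: str) -> None:
    op_chars = set(c for c in cigar if c.isalpha())
    bad = op_chars - SUPPORTED_CIGAR_OPS
    if bad:
        raise ValueError(
            f"read {qname!r}: unsupported CIGAR operation(s) {sorted(bad)} in {cigar!r}"
        )


def read_sam(path: str | os.PathLike) -> tuple[list[tuple[str, int]], list[SamRead]]:
    """Parse a SAM file of the supported dialect.

    Returns the reference list from the header and the mapped reads.
    Unmapped records are skipped (their count is not an error); any
    CIGAR operation outside M/I/D/S/=/X raises ``ValueError`` naming the
    offending record.
    """
    refs: list[tuple[str, int]] = []
    reads: list[SamRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        refs = [(name, length) for name, length in zip(fh.references, fh.lengths)]
        for seg in fh:
            if seg.is_unmapped:
                continue
            cigar = seg.cigarstring or ""
            check_cigar(cigar, seg.query_name)
            reads.append(
                SamRead(
                    qname=seg.query_name,
                    flag=seg.flag,
                    rname=seg.reference_name,
                    pos=seg.reference_start + 1,
                    cigar=cigar,
                    sequence=seg.query_sequence or "",
                    mapq=seg.mapping_quality,
                )
            )
    return refs, reads


def cigar_tuples(cigar: str) -> list[tuple[str, int]]:
    out = []
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            out.append((ch, int(n)))
            n = ""
    return out


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(path: str | os.PathLike, genes: Iterable[Gene], source: str = "paleovir") -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for g in genes:
            handle.write(
                f"{g.seqid}\t{source}\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0"
                f"\tID={g.gene_id}\n"
            )


def read_gff3(path: str | os.PathLike) -> list[Gene]:
    genes = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            genes.append(
                Gene(
                    gene_id=attrs.get("ID", f"{fields[0]}:{fields[3]}-{fields[4]}"),
                    seqid=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    return genes


# ---------------------------------------------------------------------------
# TSV


def write_tsv(path: str | os.PathLike, frame: pd.DataFrame, comment: str | None = None) -> None:
    with open(path, "w") as handle:
        if comment:
            handle.write(f"# {comment}\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
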