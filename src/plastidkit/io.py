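"""File I/O: FASTA/FASTQ via Biopython, plus GFF3/BED region writers.

In-memory reads are lightweight :class:`~plastidkit.synthsim.ReadRecord`
objects; conversion to/from Bio.SeqIO records happens only at file
boundaries.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import RegionAnnotation
from .synthsim import ReadRecord


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], description: str = "") -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description=description) for name, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        yield ReadRecord(rec.id, str(rec.seq).upper(), "".join(chr(q + 33) for q in quals))


def write_fastq(path: str | Path, reads: Iterable[ReadRecord]) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.qual]
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[tuple[ReadRecord, ReadRecord]]:
    r1 = list(read_fastq(path1))
    r2 = list(read_fastq(path2))
    if len(r1) != len(r2):
        raise ValueError("mate files have unequal record counts")
    return list(zip(r1, r2))


def write_fastq_pairs(
    path1: str | Path, path2: str | Path, pairs: Iterable[tuple[ReadRecord, ReadRecord]]
) -> None:
    pairs = list(pairs)
    write_fastq(path1, (p[0] for p in pairs))
    write_fastq(path2, (p[1] for p in pairs))


def write_regions_gff3(path: str | Path, seqid: str, annotation: RegionAnnotation) -> None:
    """Quadripartite regions as GFF3 (1-based inclusive, like the model)."""
    lines = ["##gff-version 3"]
    if not annotation.empty:
        for region in (annotation.lsc, annotation.irb, annotation.ssc, annotation.ira):
            if region is None:
                continue
            lines.append(
                "\t".join(
                    [
                        seqid,
                        "plastidkit",
                        "region",
                        str(region.start),
                        str(region.end),
                        ".",
                        "+",
                        ".",
                        f"ID={region.name};Name={region.name}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_junctions_bed(path: str | Path, seqid: str, annotation: RegionAnnotation) -> None:
    """Junction boundaries as zero-length BED features at the boundary point."""
    lines = []
    for name, (left_end, _right_start) in annotation.junctions.items():
        lines.append("\t".join([seqid, str(left_end), str(left_end), name]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
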