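"""File-format plumbing: FASTQ/FASTA/SAM/TSV/JSON readers and writers.

SAM records are written and read with pysam; FASTA/FASTQ go through
Biopython.  In-memory analysis paths use the same record attributes as
pysam's AlignedSegment, so everything downstream accepts either.
"""

from __future__ import annotations

import os
from typing import Iterator

import pysam
from Bio import SeqIO

from .synthetic_data import ReadSet, SimulatedRead


def write_fasta(records: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(readset: ReadSet, r1_path: str | os.PathLike, r2_path: str | os.PathLike) -> None:
    """Paired FASTQ with /1 and /2 name suffixes and constant Q40 qualities."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for r in readset.reads:
            fh = f1 if r.mate == 1 else f2
            qual = "I" * len(r.fastq_sequence)
            fh.write(f"@{r.query_name}/{r.mate}\n{r.fastq_sequence}\n+\n{qual}\n")


def read_fastq_sequences(*paths: str | os.PathLike) -> list[str]:
    seqs: list[str] = []
    for path in paths:
        for rec in SeqIO.parse(str(path), "fastq"):
            seqs.append(str(rec.seq))
    return seqs


def sam_header(reference_name: str, reference_length: int) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": reference_name, "LN": reference_length}],
        }
    )


def _flag(read: SimulatedRead, mate_unmapped: bool, mate_reverse: bool) -> int:
    flag = 0x1  # paired
    if read.is_unmapped:
        flag |= 0x4
    if mate_unmapped:
        flag |= 0x8
    if not (read.is_unmapped or mate_unmapped):
        flag |= 0x2
    if read.is_reverse:
        flag |= 0x10
    if mate_reverse:
        flag |= 0x20
    flag |= 0x40 if read.mate == 1 else 0x80
    return flag


def write_sam(readset: ReadSet, path: str | os.PathLike) -> None:
    """Coordinate-sorted SAM of all simulated reads (unmapped mates last)."""
    truth = readset.truth
    header = sam_header(truth.name, len(truth.reference_seq))
    by_name: dict[tuple[str, int], SimulatedRead] = {
        (r.query_name, r.mate): r for r in readset.reads
    }
    ordered = sorted(
        readset.reads,
        key=lambda r: (r.is_unmapped, r.reference_start or 0, r.query_name, r.mate),
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in ordered:
            mate = by_name.get((r.query_name, 3 - r.mate))
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.query_name
            seg.query_sequence = r.query_sequence
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(r.query_sequence))
            seg.flag = _flag(r, mate is None or mate.is_unmapped, bool(mate and mate.is_reverse))
            if r.is_unmapped:
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            else:
                seg.reference_id = 0
                seg.reference_start = r.reference_start
                seg.mapping_quality = r.mapping_quality
                seg.cigartuples = r.cigartuples
            if mate is not None and not mate.is_unmapped:
                seg.next_reference_id = 0
                seg.next_reference_start = mate.reference_start
            else:
                seg.next_reference_id = -1
                seg.next_reference_start = -1
            out.write(seg)


def read_sam(path: str | os.PathLike) -> Iterator[pysam.AlignedSegment]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        yield from fh


def write_truth_tsv(readset: ReadSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("read\tmate\thaplotype\ttemplate_start\tref_start\tcigar\n")
        for r in readset.reads:
            fh.write(
                f"{r.query_name}\t{r.mate}\t{r.origin_hap_name}\t{r.origin_start}\t"
                f"{'' if r.reference_start is None else r.reference_start}\t{r.cigar_str}\n"
            )
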