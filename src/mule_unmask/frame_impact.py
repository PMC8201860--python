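"""Coding consequences of an intragenic insertion.

Given a clean CDS (starts with ATG, ends with a stop, length a multiple of
three) and an insertion at a 1-based CDS position p (the first base
displaced rightward), the reading frame is disrupted from codon ceil(p/3).
Translation of the modified CDS from the start codon locates the first
premature termination codon (PTC); a transcript with a PTC upstream of the
native stop is flagged as a nonsense-mediated decay (NMD) target, the same
rule the read simulator uses to down-weight such transcripts.  An insert
whose length is a multiple of three and that contributes no in-frame stop
restores the original frame downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

from Bio.Seq import Seq

from .util import STOP_CODONS


@dataclass(frozen=True)
class FrameImpact:
    insertion_cds_position: int  # 1-based first displaced CDS base
    first_disrupted_codon: int  # 1-based
    first_ptc_codon: int | None  # 1-based, None if no premature stop
    frame_restored_downstream: bool
    truncated_protein_length: int | None  # aa, None without a PTC
    nmd_target: bool


def apply_insertion(cds: str, position: int, insert: str) -> str:
    """Insert a sequence before the 1-based CDS ``position``.

    ``position`` = len(cds)+1 appends after the native stop codon.
    """
    if not 1 <= position <= len(cds) + 1:
        raise ValueError(f"insertion position {position} outside 1..{len(cds) + 1}")
    return cds[: position - 1] + insert + cds[position - 1 :]


def _first_stop_codon(seq: str) -> int | None:
    """1-based index of the first in-frame stop codon, scanning whole codons."""
    for k in range(len(seq) // 3):
        if seq[3 * k : 3 * k + 3] in STOP_CODONS:
            return k + 1
    return None


def annotate_impact(cds: str, position: int, insert: str) -> FrameImpact:
    """Frame/PTC/NMD annotation of an insertion into a valid CDS."""
    if len(cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    if not cds.upper().startswith("ATG"):
        raise ValueError("CDS lacks a start codon")
    if cds[-3:].upper() not in STOP_CODONS:
        raise ValueError("CDS lacks a terminal stop codon")
    cds = cds.upper()
    insert = insert.upper()
    modified = apply_insertion(cds, position, insert)
    first_disrupted = ceil(position / 3)
    frame_restored = len(insert) % 3 == 0
    # the native stop stays in frame only if the insert preserves frame and
    # sits upstream of it; a pure append leaves it untouched
    if position == len(cds) + 1:
        native_stop_modified = len(cds) // 3
    elif frame_restored:
        native_stop_modified = (len(cds) + len(insert)) // 3
    else:
        native_stop_modified = None
    first_stop = _first_stop_codon(modified)
    if first_stop is not None and first_stop == native_stop_modified:
        first_ptc = None  # translation runs through to the native stop
    else:
        first_ptc = first_stop
    nmd = first_ptc is not None and (
        native_stop_modified is None or first_ptc < native_stop_modified
    )
    return FrameImpact(
        insertion_cds_position=position,
        first_disrupted_codon=first_disrupted,
        first_ptc_codon=first_ptc,
        frame_restored_downstream=frame_restored,
        truncated_protein_length=None if first_ptc is None else first_ptc - 1,
        nmd_target=nmd,
    )


def translate_cds(seq: str, to_stop: bool = True) -> str:
    """Standard-code translation (helper for reports; ambiguity codes -> X)."""
    trimmed = seq[: 3 * (len(seq) // 3)]
    return str(Seq(trimmed).translate(to_stop=to_stop))
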