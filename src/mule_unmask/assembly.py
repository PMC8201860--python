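"""Targeted reconstruction of an inserted sequence by iterative extension.

The two soft-clip tail consensi at an insertion breakpoint seed two contigs:
the right-clipped tails spell the insert's 5' end and are extended rightward
into the element; the left-clipped tails spell its 3' end and are extended
leftward.  Each round recruits raw reads (used unoriented) whose terminal
``k_overlap`` bases match the contig end with at most ``max_mismatch``
substitutions, and appends the strict-majority consensus of the recruited
overhangs — an exact consensus tie or thin support stops extension, trading
possible truncation for protection against chimerism.  When the two contigs
overlap they are merged, flanking reference sequence is trimmed off, and the
pure inserted sequence is reported.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .breakpoints import InsertionCall
from .util import revcomp

DEFAULT_K_OVERLAP = 31
DEFAULT_MAX_MISMATCH = 1
DEFAULT_MIN_READS = 3
DEFAULT_MIN_MERGE_OVERLAP = 40
DEFAULT_MERGE_MISMATCH = 1
DEFAULT_MAX_ROUNDS = 100
_ANCHOR = 32  # exact seed length used to position candidate overlaps
_STRONG_OVERLAP = 50  # verified overlap letting unanimous thin support extend
_FLANK_ANCHOR = 50
_FLANK_WINDOW = 2000


@dataclass
class ExtensionContig:
    """A contig grown from a clip-tail seed in one direction."""

    sequence: str
    direction: str  # "rightward" | "leftward"
    rounds: int = 0
    extension_lengths: list[int] = field(default_factory=list)
    support_per_round: list[int] = field(default_factory=list)
    status: str = "growing"  # growing | stalled | flank | incomplete


@dataclass
class InsertionSequence:
    """A reconstructed insert, or the pair of unmerged contigs."""

    sequence: str
    breakpoint: int
    status: str  # "merged" | "unmerged"
    left_rounds: int
    right_rounds: int
    overlap_length: int = 0
    overlap_mismatches: int = 0
    contigs: tuple[ExtensionContig, ExtensionContig] | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


class ReadPool:
    """Read sequences (both orientations) indexed for fast overlap search.

    All oriented reads are joined with '#' separators into one string so
    candidate overlap positions can be located with C-speed substring
    search; approximate matches are found via the pigeonhole principle
    (one half of the query must be exact for <=1 mismatch, and the scan
    simply tries both halves for any budget).
    """

    def __init__(self, sequences: Sequence[str]):
        oriented = []
        for s in sequences:
            s = s.upper()
            oriented.append(s)
            oriented.append(revcomp(s))
        self.oriented = oriented
        self.blob = "#" + "#".join(oriented) + "#"
        self.starts = []
        pos = 1
        for s in oriented:
            self.starts.append(pos)
            pos += len(s) + 1

    def _read_at(self, blob_pos: int) -> tuple[int, int]:
        """(read index, offset within read) for a blob position."""
        i = bisect_right(self.starts, blob_pos) - 1
        return i, blob_pos - self.starts[i]

    def find_approx(self, pattern: str, max_mismatch: int) -> list[tuple[int, int]]:
        """(read index, offset) of matches of `pattern` with <= max_mismatch
        substitutions, located by exact search for each pattern half."""
        k = len(pattern)
        halves = [(0, pattern[: k // 2]), (k // 2, pattern[k // 2 :])]
        hits: set[tuple[int, int]] = set()
        for off, half in halves:
            if not half:
                continue
            start = 0
            while True:
                j = self.blob.find(half, start)
                if j < 0:
                    break
                start = j + 1
                p0 = j - off
                if p0 < 1 or p0 + k > len(self.blob):
                    continue
                window = self.blob[p0 : p0 + k]
                if "#" in window:
                    continue
                mism = sum(a != b for a, b in zip(window, pattern))
                if mism <= max_mismatch:
                    hits.add(self._read_at(p0))
        return sorted(hits)


def iterative_extend(
    seed: str,
    pool: ReadPool,
    direction: str = "rightward",
    k_overlap: int = DEFAULT_K_OVERLAP,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_reads: int = DEFAULT_MIN_READS,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
    stop_sequences: Sequence[str] = (),
    context: str = "",
    flank_anchor: int = _FLANK_ANCHOR,
) -> ExtensionContig:
    """Grow a contig from ``seed`` by stringent overlap consensus.

    ``stop_sequences`` (e.g. the reference flank beyond the breakpoint) end
    the walk once the contig's leading edge lies inside one of them — the
    insert has then been fully crossed.  ``context`` is known sequence
    adjoining the seed on the side opposite to growth (for a breakpoint-
    anchored seed, the reference flank); it takes part in read recruitment
    and overlap verification but not in the reported contig.  Leftward
    extension is rightward extension of the reverse complement.
    """
    if not seed:
        raise ValueError("empty seed")
    if direction not in ("rightward", "leftward"):
        raise ValueError("direction must be 'rightward' or 'leftward'")
    flip = direction == "leftward"
    contig = revcomp(seed) if flip else seed
    ctx = revcomp(context) if flip else context
    stops = [revcomp(s) if flip else s for s in stop_sequences]
    out = ExtensionContig(sequence=seed, direction=direction)
    k = min(k_overlap, len(ctx) + len(contig))

    def in_flank(c: str) -> bool:
        tail = c[-flank_anchor:]
        return len(tail) >= flank_anchor and any(tail in s for s in stops)

    if in_flank(contig):
        out.status = "flank"
        return out
    for _ in range(max_rounds):
        full = ctx + contig
        terminal = full[-k:]
        hits = pool.find_approx(terminal, max_mismatch)
        # verify the read's whole overlap with context + contig, not just
        # the terminal window: misplaced or chimeric reads are rejected
        # here, and the verified overlap length grades the evidence strength
        overhangs: list[tuple[str, int]] = []  # (overhang, verified overlap)
        for idx, off in hits:
            read = pool.oriented[idx]
            oh = read[off + k :]
            if not oh:
                continue
            span = min(off + k, len(full))
            if _hamming(read[off + k - span : off + k], full[-span:]) > max_mismatch:
                continue
            overhangs.append((oh, span))
        if not overhangs:
            out.status = "stalled"
            break
        ext_cols: list[str] = []
        width = max(len(o) for o, _ in overhangs)
        for c in range(width):
            col = [(o[c], span) for o, span in overhangs if len(o) > c]
            if not col:
                break
            counts = Counter(b for b, _ in col).most_common()
            if len(counts) > 1 and counts[0][1] == counts[1][1]:
                break  # exact tie: refuse to guess
            if len(col) < min_reads:
                # below quorum: only unanimous, long-verified-overlap
                # evidence may extend (the thin-coverage rescue)
                # a read's effective overlap grows with each accepted column
                if len(counts) > 1 or any(
                    span + c < _STRONG_OVERLAP for _, span in col
                ):
                    break
            ext_cols.append(counts[0][0])
        if not ext_cols:
            out.status = "stalled"
            break
        contig += "".join(ext_cols)
        out.rounds += 1
        out.extension_lengths.append(len(ext_cols))
        out.support_per_round.append(len(overhangs))
        out.sequence = revcomp(contig) if flip else contig
        if in_flank(contig):
            out.status = "flank"
            break
    else:
        out.status = "incomplete"
    out.sequence = revcomp(contig) if flip else contig
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _candidate_overlaps(left: str, right: str, max_mismatch: int) -> list[tuple[int, int]]:
    """Overlaps (length, mismatches) where a suffix of `left` matches a
    prefix of `right`, located via exact anchors of the right contig's
    first bases (two staggered anchors tolerate one mismatch)."""
    cands: set[int] = set()
    for a_off in (0, _ANCHOR + 8):
        anchor = right[a_off : a_off + _ANCHOR]
        if len(anchor) < _ANCHOR:
            continue
        start = 0
        while True:
            j = left.find(anchor, start)
            if j < 0:
                break
            start = j + 1
            o = len(left) - j + a_off
            if 0 < o <= min(len(left), len(right)):
                cands.add(o)
    out = []
    for o in sorted(cands, reverse=True):
        mism = _hamming(left[-o:], right[:o])
        if mism <= max_mismatch:
            out.append((o, mism))
    return out


def _polish(merged: str, pool: ReadPool, max_read_mismatch: int = 2) -> str:
    """Full-depth consensus polish of a merged contig.

    Extension-time consensus only sees the reads recruited in each round's
    terminal window, so a column passed during a local coverage dip may
    carry a single read's sequencing error.  Re-placing every read on the
    merged contig (exact 24-mer anchors, whole-read verification at most
    ``max_read_mismatch`` substitutions, full containment required) and
    voting per column restores true local depth; ties keep the existing
    base.  The strict verification threshold keeps reverse-complement
    placements across the element's own terminal repeats out of the pileup.
    """
    import numpy as np

    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    n = len(merged)
    marr = np.frombuffer(merged.encode(), dtype="S1")
    votes = np.zeros((4, n), dtype=np.int32)
    anchor = 24
    for read in pool.oriented:
        if len(read) < 2 * anchor:
            continue
        placements: set[int] = set()
        for off in (0, anchor, 2 * anchor):
            j = merged.find(read[off : off + anchor])
            while j >= 0:
                placements.add(j - off)
                j = merged.find(read[off : off + anchor], j + 1)
        if not placements:
            continue
        rarr = np.frombuffer(read.encode(), dtype="S1")
        codes = np.searchsorted(alphabet, rarr)  # reads are ACGT-only
        for p in placements:
            if p < 0 or p + len(read) > n:
                continue
            if int((rarr != marr[p : p + len(read)]).sum()) > max_read_mismatch:
                continue
            np.add.at(votes, (codes, np.arange(p, p + len(read))), 1)
    out = list(merged)
    top = votes.argmax(axis=0)
    for i in range(n):
        col = votes[:, i]
        best = int(top[i])
        if col[best] > 0 and (col == col[best]).sum() == 1:
            out[i] = "ACGT"[best]
    return "".join(out)


def _trim_flanks(
    merged: str,
    reference: str,
    breakpoint: int,
    trim_left: bool = True,
    trim_right: bool = True,
    window: int = _FLANK_WINDOW,
) -> tuple[str, int, int]:
    """Strip reference sequence flanking the insert in a merged contig.

    The left trim is the longest prefix equal to the reference ending at the
    breakpoint; the right trim the longest suffix equal to the reference
    starting there.  Trimming applies only to extension-grown ends — a
    seed-anchored end is an exact insert boundary by construction, and
    greedy trimming there could shave true insert bases that happen to
    match the flank.
    """
    b = breakpoint
    p = s = 0
    if trim_left:
        p_max = min(len(merged) - 1, b, window)
        p = next(
            (p for p in range(p_max, 0, -1) if merged[:p] == reference[b - p : b]), 0
        )
    if trim_right:
        s_max = min(len(merged) - p - 1, len(reference) - b, window)
        s = next(
            (s for s in range(s_max, 0, -1) if merged[-s:] == reference[b : b + s]), 0
        )
    return merged[p : len(merged) - s], p, s


def assemble_insertion(
    call: InsertionCall,
    reads: Sequence[str] | ReadPool,
    reference: str,
    k_overlap: int = DEFAULT_K_OVERLAP,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_reads: int = DEFAULT_MIN_READS,
    min_merge_overlap: int = DEFAULT_MIN_MERGE_OVERLAP,
    merge_mismatch: int = DEFAULT_MERGE_MISMATCH,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
) -> InsertionSequence:
    """Reconstruct the inserted sequence behind a breakpoint call.

    Returns a merged ``InsertionSequence`` whose ``sequence`` is the pure
    insert (flanking reference trimmed), or an "unmerged" result carrying
    both contigs when the two extensions never meet within ``max_rounds``
    (the long-insert failure mode, reported rather than guessed).
    """
    pool = reads if isinstance(reads, ReadPool) else ReadPool(reads)
    b = call.breakpoint
    right_seed = call.right_cluster.well_supported_consensus(min_reads) or (
        call.right_cluster.tail_consensus.split("N")[0]
    )
    left_seed = call.left_cluster.well_supported_consensus(min_reads) or (
        call.left_cluster.tail_consensus.rsplit("N", 1)[-1]
    )
    if not right_seed or not left_seed:
        raise ValueError("call lacks usable tail consensi on both sides")
    right_flank = reference[b : b + _FLANK_WINDOW]
    left_flank = reference[max(0, b - _FLANK_WINDOW) : b]

    # degenerate short insertions: the two tail consensi already overlap
    # (or one alone spans the insert) before any extension
    seed_a = ExtensionContig(sequence=right_seed, direction="rightward", status="seed")
    seed_b = ExtensionContig(sequence=left_seed, direction="leftward", status="seed")
    best = _best_arrangement(right_seed, left_seed, min_merge_overlap, merge_mismatch)
    if best is not None:
        return _finish(best, b, reference, pool, seed_a, seed_b)

    # contig A runs 5'->3' from the insert start; contig B ends at its 3'
    # end; each is verified against the known flank behind its seed
    contig_a = iterative_extend(
        right_seed, pool, "rightward", k_overlap, max_mismatch, min_reads,
        max_rounds, stop_sequences=(right_flank,), context=left_flank,
    )
    contig_b = iterative_extend(
        left_seed, pool, "leftward", k_overlap, max_mismatch, min_reads,
        max_rounds, stop_sequences=(left_flank,), context=right_flank,
    )

    a, bseq = contig_a.sequence, contig_b.sequence
    best = _best_arrangement(a, bseq, min_merge_overlap, merge_mismatch)
    if best is None:
        # a contig that walked into the flank spans the insert by itself;
        # its other end is the seed-anchored insert boundary
        if contig_a.status == "flank":
            best = (0, 0, a, "", False, True)
        elif contig_b.status == "flank":
            best = (0, 0, bseq, "", True, False)
    if best is None:
        return InsertionSequence(
            sequence="",
            breakpoint=b,
            status="unmerged",
            left_rounds=contig_b.rounds,
            right_rounds=contig_a.rounds,
            contigs=(contig_a, contig_b),
        )
    return _finish(best, b, reference, pool, contig_a, contig_b)


def _best_arrangement(
    a: str, bseq: str, min_merge_overlap: int, merge_mismatch: int
) -> tuple[int, int, str, str, bool, bool] | None:
    """Best (overlap, mismatches, left part, right part, trim flags).

    Arrangement A-then-B covers the partial, middle-overlap case (both outer
    ends are seed-anchored insert boundaries, so nothing is trimmed);
    B-then-A the case where both contigs crossed the whole insert (both
    outer ends are extension-grown flank sequence).  Containment keeps the
    outer contig, trimming only its extension-grown side.
    """
    best = None
    for left_part, right_part, tl, tr in (
        (a, bseq, False, False),
        (bseq, a, True, True),
    ):
        for o, mism in _candidate_overlaps(left_part, right_part, merge_mismatch):
            if o >= min_merge_overlap and (best is None or o > best[0]):
                best = (o, mism, left_part, right_part, tl, tr)
    if best is None:
        for inner, outer, tl, tr in ((a, bseq, True, False), (bseq, a, False, True)):
            j = outer.find(inner[:_ANCHOR])
            if (
                j >= 0
                and j + len(inner) <= len(outer)
                and _hamming(outer[j : j + len(inner)], inner) <= merge_mismatch
            ):
                return (len(inner), 0, outer, "", tl, tr)
    return best


def _finish(
    best: tuple[int, int, str, str, bool, bool],
    breakpoint: int,
    reference: str,
    pool: ReadPool,
    contig_a: ExtensionContig,
    contig_b: ExtensionContig,
) -> InsertionSequence:
    o, mism, left_part, right_part, trim_left, trim_right = best
    merged = _polish(left_part + right_part[o:], pool)
    insert_seq, _, _ = _trim_flanks(merged, reference, breakpoint, trim_left, trim_right)
    return InsertionSequence(
        sequence=insert_seq,
        breakpoint=breakpoint,
        status="merged",
        left_rounds=contig_b.rounds,
        right_rounds=contig_a.rounds,
        overlap_length=o,
        overlap_mismatches=mism,
        contigs=(contig_a, contig_b),
    )


def write_insert_fasta(result: InsertionSequence, path) -> None:
    header = (
        f"insert breakpoint={result.breakpoint} length={result.length} "
        f"status={result.status} rounds={result.left_rounds}+{result.right_rounds}"
    )
    with open(path, "w") as fh:
        fh.write(f">{header}\n")
        for i in range(0, len(result.sequence), 80):
            fh.write(result.sequence[i : i + 80] + "\n")


def write_round_log(result: InsertionSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tround\textension_nt\tsupport\n")
        if result.contigs is None:
            return
        for contig in result.contigs:
            for i, (ext, sup) in enumerate(
                zip(contig.extension_lengths, contig.support_per_round), start=1
            ):
                fh.write(f"{contig.direction}\t{i}\t{ext}\t{sup}\n")
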