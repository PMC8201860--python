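"""Insertion-breakpoint detection from soft-clipped alignments.

A non-reference insertion leaves a characteristic signature in short-read
alignments: reads entering the inserted sequence from the left are mapped
up to the breakpoint and soft-clipped on their 3' side (their clipped tails
spell the insert's 5' end), and reads leaving it are soft-clipped on their
5' side (tails spelling the insert's 3' end).  Clustering clip positions,
building per-side tail consensi, and comparing clipped against cleanly
spanning reads yields a breakpoint call with an allele-fraction-based
zygosity estimate.

Clipped and unclipped evidence is counted over symmetric windows (a clipped
read needs a tail and an anchored match both >= ``min_clip_length``; an
unclipped read must overlap the breakpoint by >= ``min_clip_length`` on both
sides) so the insertion allele fraction is an unbiased estimate of
heterozygosity.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

RIGHT = "right"  # tail-clipped: clip follows the matched segment (insert 5' side)
LEFT = "left"  # head-clipped: clip precedes the matched segment (insert 3' side)

_REF_OPS = {0, 2, 3, 7, 8}  # M, D, N, =, X
_S = 4
_MATCH_OPS = {0, 7, 8}

DEFAULT_MIN_CLIP = 20
DEFAULT_MIN_SUPPORT = 3
DEFAULT_MERGE_WINDOW = 5
DEFAULT_HET_BAND = (0.2, 0.8)
DEFAULT_MIN_AGREEMENT = 0.6


@dataclass
class ClipCluster:
    """Soft-clip evidence merged at one reference position and side."""

    ref_position: int
    side: str  # RIGHT or LEFT
    read_names: list[str]
    tails: list[str] = field(repr=False, default_factory=list)
    tail_consensus: str = ""
    agreement: list[float] = field(repr=False, default_factory=list)
    coverage: list[int] = field(repr=False, default_factory=list)

    @property
    def support(self) -> int:
        return len(self.read_names)

    def well_supported_consensus(self, min_coverage: int = 1) -> str:
        """Consensus truncated to its contiguous run of columns with at least
        ``min_coverage`` supporting tails and no N mask, anchored at the
        breakpoint (left edge for RIGHT clusters, right edge for LEFT)."""
        keep = [
            c >= min_coverage and b != "N"
            for b, c in zip(self.tail_consensus, self.coverage)
        ]
        if self.side == RIGHT:
            n = 0
            while n < len(keep) and keep[n]:
                n += 1
            return self.tail_consensus[:n]
        n = len(keep)
        while n > 0 and keep[n - 1]:
            n -= 1
        return self.tail_consensus[n:]


@dataclass
class InsertionCall:
    """A breakpoint hypothesis pairing a right- and a left-clip cluster."""

    breakpoint: int  # 0-based: insert lies before this reference offset
    left_cluster: ClipCluster  # LEFT side (insert 3' tails)
    right_cluster: ClipCluster  # RIGHT side (insert 5' tails)
    clipped_support: int
    spanning_unclipped: int
    zygosity_call: str  # "het" | "hom" | "ambiguous"

    @property
    def insertion_allele_fraction(self) -> float:
        total = self.clipped_support + self.spanning_unclipped
        return self.clipped_support / total if total else float("nan")


def _aligned_length(cigartuples: Sequence[tuple[int, int]]) -> int:
    return sum(ln for op, ln in cigartuples if op in _MATCH_OPS)


def _reference_end(start: int, cigartuples: Sequence[tuple[int, int]]) -> int:
    return start + sum(ln for op, ln in cigartuples if op in _REF_OPS)


def _usable(aln) -> bool:
    return not (aln.is_unmapped or aln.is_secondary or aln.is_supplementary)


def _consensus(
    tails: list[str], side: str, min_agreement: float
) -> tuple[str, list[float], list[int]]:
    """Per-column majority over tails anchored at the breakpoint.

    RIGHT tails all start at the breakpoint (left-aligned); LEFT tails all
    end there (right-aligned).  Columns whose majority base falls below
    ``min_agreement`` are masked as N.  Returns (consensus, agreement
    fraction per column, tail coverage per column).
    """
    width = max(len(t) for t in tails)
    cols: list[str] = []
    fracs: list[float] = []
    covs: list[int] = []
    for i in range(width):
        bases = []
        for t in tails:
            j = i if side == RIGHT else len(t) - width + i
            if 0 <= j < len(t):
                bases.append(t[j])
        counts = Counter(bases)
        base, n = counts.most_common(1)[0]
        frac = n / len(bases)
        cols.append(base if frac >= min_agreement else "N")
        fracs.append(frac)
        covs.append(len(bases))
    return "".join(cols), fracs, covs


def collect_clips(
    alignments: Iterable,
    min_clip_length: int = DEFAULT_MIN_CLIP,
    min_base_agreement: float = DEFAULT_MIN_AGREEMENT,
    merge_window: int = DEFAULT_MERGE_WINDOW,
) -> list[ClipCluster]:
    """Cluster soft-clipped read ends by clip position and side.

    ``alignments`` must be sorted by reference position (SAM coordinate
    order); unmapped/secondary/supplementary records are skipped with a
    logged count.  A clipped read contributes only if both its clipped tail
    and its aligned portion are at least ``min_clip_length``; a read clipped
    on both ends contributes both tails; duplicate read names are counted
    once per (position, side).
    """
    if min_clip_length < 1:
        raise ValueError("min_clip_length must be >= 1")
    evidence: dict[str, list[tuple[int, str, str]]] = {RIGHT: [], LEFT: []}
    skipped = 0
    last_start = -1
    for aln in alignments:
        if not _usable(aln):
            skipped += 1
            continue
        if aln.reference_start < last_start:
            raise ValueError("alignments are not sorted by reference position")
        last_start = aln.reference_start
        cig = aln.cigartuples
        if cig is None or _aligned_length(cig) < min_clip_length:
            continue
        seq = aln.query_sequence
        if cig[0][0] == _S and cig[0][1] >= min_clip_length:
            evidence[LEFT].append(
                (aln.reference_start, aln.query_name, seq[: cig[0][1]])
            )
        if cig[-1][0] == _S and cig[-1][1] >= min_clip_length:
            end = _reference_end(aln.reference_start, cig)
            evidence[RIGHT].append((end, aln.query_name, seq[-cig[-1][1] :]))
    if skipped:
        logger.info("collect_clips: skipped %d unusable records", skipped)

    clusters: list[ClipCluster] = []
    for side, items in evidence.items():
        items.sort(key=lambda t: t[0])
        group: list[tuple[int, str, str]] = []
        for item in items + [(None, "", "")]:  # sentinel flush
            if group and (item[0] is None or item[0] - group[-1][0] > merge_window):
                positions = Counter(p for p, _, _ in group)
                ref_pos = min(
                    positions, key=lambda p: (-positions[p], p)
                )  # majority position, ties leftmost
                seen: set[str] = set()
                names, tails = [], []
                for _, name, tail in group:
                    if name not in seen:
                        seen.add(name)
                        names.append(name)
                        tails.append(tail)
                cons, fracs, covs = _consensus(tails, side, min_base_agreement)
                clusters.append(
                    ClipCluster(ref_pos, side, names, tails, cons, fracs, covs)
                )
                group = []
            if item[0] is not None:
                group.append(item)
    clusters.sort(key=lambda c: (c.ref_position, c.side))
    return clusters


def _count_spanning(alignments: Iterable, breakpoint: int, window: int) -> int:
    """Unclipped reads whose matched alignment covers breakpoint +/- window."""
    seen: set[str] = set()
    lo, hi = breakpoint - window, breakpoint + window
    for aln in alignments:
        if not _usable(aln) or aln.cigartuples is None:
            continue
        # a clipped read can still span cleanly elsewhere: the requirement is
        # only that one matched block contains the whole window
        pos = aln.reference_start
        covered = False
        for op, ln in aln.cigartuples:
            if op in _MATCH_OPS and pos <= lo and pos + ln >= hi:
                covered = True
            if op in _REF_OPS:
                pos += ln
        if covered and aln.query_name not in seen:
            seen.add(aln.query_name)
    return len(seen)


def call_insertions(
    clusters: list[ClipCluster],
    alignments: Iterable | None = None,
    min_support: int = DEFAULT_MIN_SUPPORT,
    merge_window: int = DEFAULT_MERGE_WINDOW,
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
    min_clip_length: int = DEFAULT_MIN_CLIP,
) -> list[InsertionCall]:
    """Pair right- and left-clip clusters into insertion calls.

    Pairing is positional (within ``merge_window``); the two tail consensi
    are deliberately not required to overlap each other, since for inserts
    longer than the read length they sample opposite ends of the insert.
    ``alignments`` (re-iterable) supplies the unclipped spanning-read count
    used for the allele fraction; without it, zygosity is "ambiguous".
    """
    alignments = list(alignments) if alignments is not None else None
    rights = [c for c in clusters if c.side == RIGHT]
    lefts = [c for c in clusters if c.side == LEFT]
    calls: list[InsertionCall] = []
    used: set[int] = set()
    for rc in rights:
        best = None
        for i, lc in enumerate(lefts):
            if i in used or abs(lc.ref_position - rc.ref_position) > merge_window:
                continue
            if best is None or abs(lc.ref_position - rc.ref_position) < abs(
                lefts[best].ref_position - rc.ref_position
            ):
                best = i
        if best is None:
            continue
        used.add(best)
        lc = lefts[best]
        # a long insertion presents two junctions; averaging the per-side
        # support compares one junction's worth of clipped evidence with
        # the single spanning window, keeping the allele fraction unbiased
        support = round((len(set(rc.read_names)) + len(set(lc.read_names))) / 2)
        if support < min_support:
            continue
        breakpoint = rc.ref_position
        spanning = (
            _count_spanning(alignments, breakpoint, min_clip_length)
            if alignments is not None
            else 0
        )
        total = support + spanning
        if alignments is None or total == 0:
            zygosity = "ambiguous"
        else:
            af = support / total
            lo, hi = het_band
            if lo <= af <= hi:
                zygosity = "het"
            elif af > hi:
                zygosity = "hom"
            else:
                zygosity = "ambiguous"
        calls.append(
            InsertionCall(
                breakpoint=breakpoint,
                left_cluster=lc,
                right_cluster=rc,
                clipped_support=support,
                spanning_unclipped=spanning,
                zygosity_call=zygosity,
            )
        )
    calls.sort(key=lambda c: c.breakpoint)
    return calls


def detect_insertions(
    alignments: Iterable,
    min_clip_length: int = DEFAULT_MIN_CLIP,
    min_base_agreement: float = DEFAULT_MIN_AGREEMENT,
    min_support: int = DEFAULT_MIN_SUPPORT,
    merge_window: int = DEFAULT_MERGE_WINDOW,
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
) -> list[InsertionCall]:
    """collect_clips + call_insertions over one pass-materialized input."""
    alns = list(alignments)
    clusters = collect_clips(alns, min_clip_length, min_base_agreement, merge_window)
    return call_insertions(
        clusters, alns, min_support, merge_window, het_band, min_clip_length
    )


def write_calls_tsv(calls: list[InsertionCall], path) -> None:
    """Breakpoints reported 1-based ("inserted after nucleotide N")."""
    with open(path, "w") as fh:
        fh.write(
            "breakpoint_1based\tclipped_support\tspanning_unclipped\t"
            "allele_fraction\tzygosity\tright_tail_consensus\tleft_tail_consensus\n"
        )
        for c in calls:
            fh.write(
                f"{c.breakpoint}\t{c.clipped_support}\t{c.spanning_unclipped}\t"
                f"{c.insertion_allele_fraction:.4f}\t{c.zygosity_call}\t"
                f"{c.right_cluster.tail_consensus}\t{c.left_cluster.tail_consensus}\n"
            )


def write_calls_vcf(calls: list[InsertionCall], reference_name: str, path) -> None:
    """Minimal symbolic-ALT VCF (<INS>) for interoperability."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=INS,Description="Insertion relative to the reference">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="Breakpoint">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Clipped reads">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Insertion allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            fh.write(
                f"{reference_name}\t{c.breakpoint}\t.\tN\t<INS>\t.\tPASS\t"
                f"END={c.breakpoint};SUPPORT={c.clipped_support};"
                f"AF={c.insertion_allele_fraction:.4f}\n"
            )
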