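"""Structural annotation of a reconstructed insert as a DNA transposon.

Two lines of evidence classify an insert: imperfect terminal inverted
repeats (TIRs) — the hallmark of DNA transposons, whose 3' terminus is the
near reverse complement of the 5' terminus — and overall identity to known
full-length elements, which also reveals whether the insert is a truncated
copy (the resistant clones' element lacks its 5' end).

TIR search is anchored at the element termini and considers substitutions
only; the hit is the maximal-scoring terminal alignment (match +1, mismatch
-3) under a mismatch-fraction cap.  The score criterion, rather than
"longest length passing the cap", prevents chance complementarity just
inside the element from inflating the repeat by tens of bases when the
mismatch budget is slack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .util import revcomp

DEFAULT_MIN_TIR = 15
DEFAULT_MAX_MISMATCH_FRACTION = 0.1
DEFAULT_SEARCH_WINDOW = 300
DEFAULT_MIN_IDENTITY = 0.9
_MISMATCH_PENALTY = 3
_END_TOLERANCE = 5  # nt of slack when deciding whether an alignment reaches a terminus


@dataclass(frozen=True)
class TIRHit:
    """A terminal-inverted-repeat pair on an element."""

    left_interval: tuple[int, int]  # 0-based half-open on the element
    right_interval: tuple[int, int]
    length: int
    mismatches: int

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.length


@dataclass
class TEAnnotation:
    """Library comparison and truncation classification of an element."""

    element_length: int
    tir: TIRHit | None = None
    library_matches: list[tuple[str, float, tuple[int, int]]] = field(default_factory=list)
    best_match: str | None = None
    truncation_end: str = "none"  # "5p" | "3p" | "none"
    bases_missing: int = 0


def find_tirs(
    element: str,
    min_length: int = DEFAULT_MIN_TIR,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
    search_window: int = DEFAULT_SEARCH_WINDOW,
) -> TIRHit | None:
    """Best terminal-inverted-repeat pair, or None.

    Alignment column i pairs element[i] with the complement of
    element[-1-i]; candidate lengths run from ``min_length`` up to
    ``search_window`` (capped at half the element).  Among lengths whose
    mismatch fraction is within ``max_mismatch_fraction``, the
    maximal-scoring one (+1/-3, ties to the longer) is returned.
    """
    n = len(element)
    if n < 2 * min_length:
        raise ValueError("element shorter than twice the minimum TIR length")
    lmax = min(search_window, n // 2)
    prefix = np.frombuffer(element[:lmax].encode(), dtype="S1")
    suffix_rc = np.frombuffer(revcomp(element[n - lmax :]).encode(), dtype="S1")
    mismatch_cum = np.concatenate([[0], np.cumsum(prefix != suffix_rc)])
    lengths = np.arange(min_length, lmax + 1)
    mism = mismatch_cum[lengths]
    ok = mism <= max_mismatch_fraction * lengths
    if not ok.any():
        return None
    scores = lengths - (1 + _MISMATCH_PENALTY) * mism
    scores = np.where(ok, scores, np.iinfo(np.int64).min)
    best = int(np.argmax(scores))  # argmax returns the first = shortest...
    # ...so resolve score ties toward the longer length explicitly
    best_candidates = np.nonzero(scores == scores[best])[0]
    best = int(best_candidates[-1])
    L = int(lengths[best])
    return TIRHit(
        left_interval=(0, L),
        right_interval=(n - L, n),
        length=L,
        mismatches=int(mism[best]),
    )


def _align(query: str, target: str) -> tuple[int, tuple[int, int]]:
    """(edit distance, target span half-open) of query within target.

    Infix alignment (free end gaps on the target) unless the two are the
    same length, where a plain global alignment keeps identity symmetric.
    """
    mode = "NW" if len(query) == len(target) else "HW"
    res = edlib.align(query, target, mode=mode, task="locations")
    if mode == "NW":
        return res["editDistance"], (0, len(target))
    start, end = res["locations"][0]
    return res["editDistance"], (start, end + 1)


def compare_to_library(
    element: str,
    library: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_tir_length: int = DEFAULT_MIN_TIR,
    max_tir_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
    tir_search_window: int = DEFAULT_SEARCH_WINDOW,
) -> TEAnnotation:
    """Annotate an element against a library of full-length elements.

    For each library entry the shorter sequence is aligned within the
    longer; identity is reported relative to the shorter.  If the best
    match is a longer entry and the element aligns as its suffix, the
    element is classified 5'-truncated with ``bases_missing`` equal to the
    unaligned library prefix (symmetrically for 3').
    """
    if not library:
        raise ValueError("TE library is empty")
    ann = TEAnnotation(element_length=len(element))
    if len(element) >= 2 * min_tir_length:
        ann.tir = find_tirs(
            element, min_tir_length, max_tir_mismatch_fraction, tir_search_window
        )
    best_identity = -1.0
    best_entry = None
    for name, seq in library.items():
        if len(element) <= len(seq):
            dist, span = _align(element, seq)
            identity = 1.0 - dist / len(element)
        else:
            dist, span = _align(seq, element)
            identity = 1.0 - dist / len(seq)
        ann.library_matches.append((name, 100.0 * identity, span))
        if identity > best_identity:
            best_identity = identity
            best_entry = (name, seq, span)
    ann.library_matches.sort(key=lambda t: -t[1])
    if best_entry is None or best_identity < min_identity:
        return ann
    name, seq, (start, end) = best_entry
    ann.best_match = name
    if len(seq) > len(element):
        reaches_end = end >= len(seq) - _END_TOLERANCE
        reaches_start = start <= _END_TOLERANCE
        if reaches_end and not reaches_start:
            ann.truncation_end = "5p"
            ann.bases_missing = start
        elif reaches_start and not reaches_end:
            ann.truncation_end = "3p"
            ann.bases_missing = len(seq) - end
    return ann


def write_annotation_tsv(ann: TEAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("field\tvalue\n")
        fh.write(f"element_length\t{ann.element_length}\n")
        if ann.tir is not None:
            fh.write(f"tir_length\t{ann.tir.length}\n")
            fh.write(f"tir_mismatches\t{ann.tir.mismatches}\n")
            fh.write(f"tir_identity\t{ann.tir.identity:.4f}\n")
        else:
            fh.write("tir_length\t0\n")
        fh.write(f"best_match\t{ann.best_match or ''}\n")
        for name, pid, (s, e) in ann.library_matches:
            fh.write(f"library_match\t{name}:{pid:.1f}%:{s}-{e}\n")
        fh.write(f"truncation_end\t{ann.truncation_end}\n")
        fh.write(f"bases_missing\t{ann.bases_missing}\n")
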