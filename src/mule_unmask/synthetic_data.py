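"""Ground-truth simulation of a diploid sodium-channel-like locus.

The generator emulates the genetic situation found in pyrethroid-resistant
green peach aphid clones: a single-copy gene whose coding sequence carries,
on one haplotype, a heterozygous ~2 kb DNA transposon with imperfect
terminal inverted repeats (TIRs), and on the other haplotype two linked
resistance point mutations (kdr/skdr analogues).  Paired-end DNA reads
drawn from the two haplotypes produce soft-clipped alignments at the
insertion breakpoint; RNA reads drawn from the spliced transcripts are
down-weighted for the premature-termination-codon (PTC) bearing allele,
emulating nonsense-mediated decay (NMD).

Every read carries an analytically computed truth alignment against the
insertion-free reference, so downstream detectors and assemblers can be
tested without an external aligner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .util import (
    DNA,
    STOP_CODONS,
    complement_base,
    mutate,
    random_codons,
    random_seq,
    revcomp,
)

# canonical clone archetypes: haplotype alphabet S (wild type, expressed),
# R (kdr+skdr, expressed), M (wild type silenced by the TE insertion)
ARCHETYPES: dict[str, tuple[str, str]] = {
    "1X": ("S", "S"),
    "4H": ("S", "R"),
    "62H2": ("M", "R"),
    "88H2": ("M", "R"),
    "92H6": ("R", "R"),
}

# pysam-compatible CIGAR operation codes
_OP_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4}
_QUERY_OPS = frozenset("MIS")


@dataclass(frozen=True)
class VariantSite:
    """A biallelic substitution site on the reference locus.

    ``position`` is the 0-based genomic offset; ``cds_position`` the 1-based
    offset of the same base within the spliced CDS; ``cds_codon`` the 1-based
    codon index.
    """

    position: int
    ref_base: str
    alt_base: str
    label: str
    cds_position: int | None = None
    cds_codon: int | None = None

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError(f"site {self.label}: ref and alt must differ")


@dataclass(frozen=True)
class TESpec:
    """A DNA transposon element.

    ``tir_length``/``tir_mismatches`` describe the terminal inverted repeats
    of the *full-length parent*; if ``truncated_5p`` > 0 the element is that
    parent with the first ``truncated_5p`` bases removed (so its own 5' TIR
    is broken, as for a 5'-truncated element).
    """

    sequence: str
    tir_length: int
    tir_mismatches: int
    truncated_5p: int = 0
    name: str = "TE"

    def __len__(self) -> int:
        return len(self.sequence)


def _spaced_positions(
    m: int, lo: int, hi: int, min_gap: int, rng: np.random.Generator
) -> list[int]:
    """m positions in [lo, hi] with pairwise distance >= min_gap."""
    span = hi - lo
    if m == 0:
        return []
    if (m - 1) * min_gap > span:
        raise ValueError("too many TIR mismatches for the requested TIR length")
    # sample the slack between consecutive positions
    slack = span - (m - 1) * min_gap
    cuts = np.sort(rng.integers(0, slack + 1, size=m))
    return [lo + int(c) + i * min_gap for i, c in enumerate(cuts)]


def make_te(
    length: int,
    tir_length: int,
    tir_mismatch_count: int,
    seed: int,
    name: str = "TE",
) -> TESpec:
    """Random DNA transposon with imperfect terminal inverted repeats.

    The last ``tir_length`` bases are the reverse complement of the first
    ``tir_length`` bases except at exactly ``tir_mismatch_count`` alignment
    columns.  Mismatch columns are spaced at least 5 apart and kept off the
    TIR's inner edge, and (when interior sequence allows) the two alignment
    columns just inside the element are forced non-complementary, so the
    planted TIR is unambiguously the maximal terminal repeat.
    """
    if tir_length < 0 or length < 2 * tir_length:
        raise ValueError("element length must be at least twice the TIR length")
    if tir_length and tir_mismatch_count >= tir_length:
        raise ValueError("TIR mismatch count must be smaller than the TIR length")
    rng = np.random.default_rng(seed)
    seq = list(random_seq(length, rng))
    if tir_length == 0:
        return TESpec("".join(seq), 0, 0, name=name)
    # plant a perfect TIR, then inject mismatches on the left copy
    left = seq[:tir_length]
    seq[length - tir_length :] = list(revcomp("".join(left)))
    for col in _spaced_positions(
        tir_mismatch_count, 0, max(tir_length - 5, 0), 5, rng
    ):
        want_not = complement_base(seq[length - 1 - col])
        seq[col] = rng.choice([b for b in DNA if b != want_not])
    # break complementarity just inside the element (columns t and t+1)
    for col in (tir_length, tir_length + 1):
        partner = length - 1 - col
        if col < partner and col < length // 2 and partner >= length - length // 2:
            bad = complement_base(seq[partner])
            if seq[col] == bad:
                seq[col] = rng.choice([b for b in DNA if b != bad])
    return TESpec("".join(seq), tir_length, tir_mismatch_count, name=name)


@dataclass(frozen=True)
class HaplotypeSpec:
    """One haplotype: substitution alleles plus an optional TE insertion.

    ``insertion`` is ``(breakpoint, te)`` with a 0-based breakpoint meaning
    the element sits immediately before that reference offset.
    """

    name: str
    variant_alleles: dict[int, str] = field(default_factory=dict)
    insertion: tuple[int, TESpec] | None = None


@dataclass(frozen=True)
class LocusConfig:
    """Parameters of the simulated locus.

    Defaults reproduce the study geometry: an ~8 kb gene with a 4.8 kb CDS
    over three exons, a TE breakpoint at CDS nt 2,360 (codon 787), and the
    skdr/kdr analogue sites 346 and 634 nt downstream of the breakpoint on
    the same exon.  The default element is the 5'-truncated (2,076 nt) form
    of a full-length parent carrying 109-nt imperfect TIRs.
    """

    archetype: str | None = "62H2"
    seed: int = 0
    locus_length: int = 8000
    cds_intervals: tuple[tuple[int, int], ...] = ((500, 2000), (2600, 4400), (5000, 6500))
    breakpoint_cds_position: int = 2360  # 1-based first displaced CDS base
    site_offsets: tuple[int, ...] = (346, 634)  # nt downstream of the breakpoint
    site_labels: tuple[str, ...] = ("skdr", "kdr")
    te_length: int = 2076
    te_tir_length: int = 109
    te_tir_mismatches: int = 5
    te_truncated_5p: int = 500
    haplotype_names: tuple[str, str] | None = None


@dataclass(frozen=True)
class LocusTruth:
    """Full ground truth for a simulated diploid locus."""

    reference_seq: str
    cds_intervals: tuple[tuple[int, int], ...]
    sites: tuple[VariantSite, ...]
    haplotypes: tuple[HaplotypeSpec, HaplotypeSpec]
    te_library: dict[str, str] = field(default_factory=dict)
    archetype: str | None = None
    name: str = "locus"

    # ---------------- coordinate machinery ----------------

    @cached_property
    def cds_map(self) -> list[int]:
        """Genomic offset of each CDS base (ascending)."""
        out: list[int] = []
        for start, end in self.cds_intervals:
            out.extend(range(start, end))
        return out

    @cached_property
    def cds_seq(self) -> str:
        return "".join(self.reference_seq[i] for i in self.cds_map)

    @property
    def cds_length(self) -> int:
        return len(self.cds_map)

    def cds_to_genomic(self, cds_offset0: int) -> int:
        return self.cds_map[cds_offset0]

    @property
    def insertion(self) -> tuple[int, TESpec] | None:
        """(genomic breakpoint, element) of the first inserted haplotype."""
        for hap in self.haplotypes:
            if hap.insertion is not None:
                return hap.insertion
        return None

    def hap_cds(self, i: int) -> str:
        """Spliced CDS of haplotype i, with variants but no insertion."""
        hap = self.haplotypes[i]
        bases = list(self.cds_seq)
        g2c = {g: c for c, g in enumerate(self.cds_map)}
        for pos, allele in hap.variant_alleles.items():
            if pos in g2c:
                bases[g2c[pos]] = allele
        return "".join(bases)

    def hap_genome(self, i: int) -> str:
        hap = self.haplotypes[i]
        seq = list(self.reference_seq)
        for pos, allele in hap.variant_alleles.items():
            seq[pos] = allele
        out = "".join(seq)
        if hap.insertion is not None:
            b, te = hap.insertion
            out = out[:b] + te.sequence + out[b:]
        return out

    def genome_blocks(self, i: int) -> list[tuple[int, int, int | None]]:
        """(hap_start, hap_end, ref_start|None) blocks of haplotype i's genome."""
        hap = self.haplotypes[i]
        n = len(self.reference_seq)
        if hap.insertion is None:
            return [(0, n, 0)]
        b, te = hap.insertion
        L = len(te)
        return [(0, b, 0), (b, b + L, None), (b + L, n + L, b)]

    def hap_mrna(self, i: int) -> str:
        """Spliced mature transcript (CDS only) of haplotype i."""
        cds = self.hap_cds(i)
        hap = self.haplotypes[i]
        if hap.insertion is None:
            return cds
        b, te = hap.insertion
        cds_off = self._insertion_cds_offset(b)
        return cds[:cds_off] + te.sequence + cds[cds_off:]

    def _insertion_cds_offset(self, genomic_breakpoint: int) -> int:
        """0-based CDS offset of the first displaced CDS base."""
        off = 0
        for start, end in self.cds_intervals:
            if start <= genomic_breakpoint < end:
                return off + (genomic_breakpoint - start)
            off += end - start
        raise ValueError("insertion breakpoint falls outside the CDS")

    @property
    def insertion_cds_position(self) -> int | None:
        """1-based CDS index of the first displaced base, or None."""
        ins = self.insertion
        if ins is None:
            return None
        return self._insertion_cds_offset(ins[0]) + 1

    def mrna_blocks(self, i: int) -> list[tuple[int, int, int | None]]:
        """(mrna_start, mrna_end, ref_genomic_start|None) blocks of the transcript."""
        hap = self.haplotypes[i]
        pieces: list[tuple[int, int | None]] = []  # (length, ref_start|None)
        if hap.insertion is None:
            for start, end in self.cds_intervals:
                pieces.append((end - start, start))
        else:
            b, te = hap.insertion
            for start, end in self.cds_intervals:
                if start <= b < end:
                    if b > start:
                        pieces.append((b - start, start))
                    pieces.append((len(te), None))
                    if end > b:
                        pieces.append((end - b, b))
                else:
                    pieces.append((end - start, start))
        blocks = []
        q = 0
        for length, ref in pieces:
            blocks.append((q, q + length, ref))
            q += length
        return blocks

    def is_nmd_target(self, i: int) -> bool:
        """True if haplotype i's transcript carries a PTC (stop upstream of the
        native final codon in the frame read from the start codon)."""
        mrna = self.hap_mrna(i)
        n_codons = len(mrna) // 3
        for k in range(n_codons):
            if mrna[3 * k : 3 * k + 3] in STOP_CODONS:
                return k + 1 < n_codons or len(mrna) % 3 != 0
        return False

    # ---------------- serialization ----------------

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "archetype": self.archetype,
            "reference_seq": self.reference_seq,
            "cds_intervals": [list(iv) for iv in self.cds_intervals],
            "sites": [
                {
                    "position": s.position,
                    "ref_base": s.ref_base,
                    "alt_base": s.alt_base,
                    "label": s.label,
                    "cds_position": s.cds_position,
                    "cds_codon": s.cds_codon,
                }
                for s in self.sites
            ],
            "haplotypes": [
                {
                    "name": h.name,
                    "variant_alleles": {str(k): v for k, v in h.variant_alleles.items()},
                    "insertion": None
                    if h.insertion is None
                    else {
                        "breakpoint": h.insertion[0],
                        "sequence": h.insertion[1].sequence,
                        "tir_length": h.insertion[1].tir_length,
                        "tir_mismatches": h.insertion[1].tir_mismatches,
                        "truncated_5p": h.insertion[1].truncated_5p,
                        "te_name": h.insertion[1].name,
                    },
                }
                for h in self.haplotypes
            ],
            "te_library": self.te_library,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LocusTruth":
        d = json.loads(text)
        sites = tuple(VariantSite(**s) for s in d["sites"])
        haps = []
        for h in d["haplotypes"]:
            ins = None
            if h["insertion"] is not None:
                hi = h["insertion"]
                ins = (
                    hi["breakpoint"],
                    TESpec(
                        hi["sequence"],
                        hi["tir_length"],
                        hi["tir_mismatches"],
                        hi["truncated_5p"],
                        hi.get("te_name", "TE"),
                    ),
                )
            haps.append(
                HaplotypeSpec(
                    h["name"],
                    {int(k): v for k, v in h["variant_alleles"].items()},
                    ins,
                )
            )
        return cls(
            reference_seq=d["reference_seq"],
            cds_intervals=tuple(tuple(iv) for iv in d["cds_intervals"]),
            sites=sites,
            haplotypes=tuple(haps),
            te_library=d.get("te_library", {}),
            archetype=d.get("archetype"),
            name=d.get("name", "locus"),
        )


def build_locus(config: LocusConfig) -> LocusTruth:
    """Construct a ground-truth diploid locus for a clone archetype.

    Raises a ValueError for unknown archetypes or a breakpoint/site geometry
    that does not fit inside the annotated CDS.
    """
    if config.haplotype_names is not None:
        hap_names = config.haplotype_names
    else:
        if config.archetype not in ARCHETYPES:
            raise ValueError(f"unknown clone archetype: {config.archetype!r}")
        hap_names = ARCHETYPES[config.archetype]

    rng = np.random.default_rng(config.seed)
    cds_len = sum(e - s for s, e in config.cds_intervals)
    if cds_len % 3:
        raise ValueError("CDS length must be a multiple of 3")
    for s, e in config.cds_intervals:
        if not (0 <= s < e <= config.locus_length):
            raise ValueError("CDS interval outside the locus")

    needs_insertion = "M" in hap_names
    bp = config.breakpoint_cds_position
    if not (1 <= bp <= cds_len):
        if needs_insertion:
            raise ValueError("insertion breakpoint outside the CDS")
    for off in config.site_offsets:
        if bp + off > cds_len:
            raise ValueError("variant site outside the CDS")

    # reference: random backbone, CDS codons (no internal stops) spliced in
    backbone = list(random_seq(config.locus_length, rng))
    cds = "ATG" + random_codons(cds_len // 3 - 2, rng) + "TAA"
    cds_map: list[int] = []
    for s, e in config.cds_intervals:
        cds_map.extend(range(s, e))
    for cds_off, g in enumerate(cds_map):
        backbone[g] = cds[cds_off]
    reference = "".join(backbone)

    # variant sites: resistance alleles downstream of the breakpoint
    sites = []
    for off, label in zip(config.site_offsets, config.site_labels):
        cds_pos = bp + off  # 1-based
        cds_off = cds_pos - 1
        ref_base = cds[cds_off]
        codon_idx = cds_off // 3
        codon = list(cds[3 * codon_idx : 3 * codon_idx + 3])
        within = cds_off % 3
        choices = []
        for b in DNA:
            if b == ref_base:
                continue
            codon[within] = b
            if "".join(codon) not in STOP_CODONS:
                choices.append(b)
        codon[within] = ref_base
        alt = str(rng.choice(choices))
        sites.append(
            VariantSite(
                position=cds_map[cds_off],
                ref_base=ref_base,
                alt_base=alt,
                label=label,
                cds_position=cds_pos,
                cds_codon=codon_idx + 1,
            )
        )

    # transposon: truncated form of a full-length parent with intact TIRs
    te_seed = int(rng.integers(0, 2**31 - 1))
    parent = make_te(
        config.te_length + config.te_truncated_5p,
        config.te_tir_length,
        config.te_tir_mismatches,
        seed=te_seed,
        name="MULE_like_full",
    )
    te = TESpec(
        parent.sequence[config.te_truncated_5p :],
        parent.tir_length,
        parent.tir_mismatches,
        truncated_5p=config.te_truncated_5p,
        name="MULE_like",
    )
    genomic_bp = cds_map[bp - 1]

    alt_alleles = {s.position: s.alt_base for s in sites}
    defs = {
        "S": HaplotypeSpec("S"),
        "R": HaplotypeSpec("R", alt_alleles),
        "M": HaplotypeSpec("M", {}, (genomic_bp, te)),
    }
    try:
        haplotypes = tuple(defs[n] for n in hap_names)
    except KeyError as exc:
        raise ValueError(f"unknown haplotype name: {exc.args[0]!r}") from exc

    return LocusTruth(
        reference_seq=reference,
        cds_intervals=tuple(config.cds_intervals),
        sites=tuple(sites),
        haplotypes=haplotypes,  # type: ignore[arg-type]
        te_library={parent.name: parent.sequence},
        archetype=config.archetype if config.haplotype_names is None else None,
    )


# ---------------- read simulation ----------------


@dataclass
class SimulatedRead:
    """One sequenced read plus its analytically derived truth alignment.

    ``query_sequence`` is reference-oriented (as it would appear in a SAM
    record); ``fastq_sequence`` is sequencer-oriented (reverse-complemented
    for minus-strand reads).  ``cigartuples`` uses pysam operation codes and
    is None for unmapped reads.
    """

    query_name: str
    mate: int
    fastq_sequence: str
    query_sequence: str
    origin_haplotype: int
    origin_hap_name: str
    origin_start: int  # template (haplotype/transcript) coordinate
    is_reverse: bool
    reference_start: int | None
    cigartuples: list[tuple[int, int]] | None
    mapping_quality: int = 60
    is_secondary: bool = False
    is_supplementary: bool = False

    @property
    def is_unmapped(self) -> bool:
        return self.reference_start is None

    @property
    def query_qualities(self) -> list[int]:
        return [40] * len(self.query_sequence)

    @property
    def cigar_str(self) -> str:
        if self.cigartuples is None:
            return "*"
        names = "MIDNS"
        return "".join(f"{ln}{names[op]}" for op, ln in self.cigartuples)


@dataclass
class ReadSet:
    """All reads simulated from one locus, plus provenance."""

    reads: list[SimulatedRead]
    mode: str
    truth: LocusTruth
    read_length: int
    seed: int

    def sorted_alignments(self) -> list[SimulatedRead]:
        """Mapped reads in reference-coordinate order (SAM sort order)."""
        return sorted(
            (r for r in self.reads if not r.is_unmapped),
            key=lambda r: (r.reference_start, r.query_name, r.mate),
        )

    def sequences(self) -> list[str]:
        """Sequencer-oriented read sequences (the FASTQ view)."""
        return [r.fastq_sequence for r in self.reads]


def _truth_alignment(
    blocks: list[tuple[int, int, int | None]], qstart: int, qlen: int
) -> tuple[int | None, list[tuple[int, int]] | None]:
    """Alignment of template interval [qstart, qstart+qlen) to the reference.

    Walks the haplotype/transcript block map; bases falling in inserted
    sequence become soft clips, intron jumps become N.  Returns
    (reference_start, cigartuples) or (None, None) when no base maps.
    """
    qend = qstart + qlen
    ops: list[tuple[str, int, int | None]] = []  # (op, len, ref_start|None)
    for bstart, bend, ref in blocks:
        lo, hi = max(qstart, bstart), min(qend, bend)
        if lo >= hi:
            continue
        if ref is None:
            ops.append(("I", hi - lo, None))
        else:
            ops.append(("M", hi - lo, ref + (lo - bstart)))
    # insert N between mapped blocks separated on the reference
    with_gaps: list[tuple[str, int, int | None]] = []
    prev_ref_end = None
    for op, ln, ref in ops:
        if op == "M" and prev_ref_end is not None and ref > prev_ref_end:
            with_gaps.append(("N", ref - prev_ref_end, None))
        with_gaps.append((op, ln, ref))
        if op == "M":
            prev_ref_end = ref + ln
    # choose the mapped core: contiguous M/N run with the largest M total
    runs: list[tuple[int, int, int]] = []  # (start_idx, end_idx, m_total)
    i = 0
    while i < len(with_gaps):
        if with_gaps[i][0] in ("M", "N"):
            j = i
            m_total = 0
            while j < len(with_gaps) and with_gaps[j][0] in ("M", "N"):
                if with_gaps[j][0] == "M":
                    m_total += with_gaps[j][1]
                j += 1
            runs.append((i, j, m_total))
            i = j
        else:
            i += 1
    runs = [r for r in runs if r[2] > 0]
    if not runs:
        return None, None
    start_idx, end_idx, _ = max(runs, key=lambda r: r[2])
    left_clip = sum(ln for op, ln, _ in with_gaps[:start_idx] if op in _QUERY_OPS)
    right_clip = sum(ln for op, ln, _ in with_gaps[end_idx:] if op in _QUERY_OPS)
    core = with_gaps[start_idx:end_idx]
    # trim N at the core edges (an alignment cannot start/end with N)
    while core and core[0][0] == "N":
        core.pop(0)
    while core and core[-1][0] == "N":
        core.pop()
    ref_start = next(ref for op, ln, ref in core if op == "M")
    cig: list[tuple[int, int]] = []
    if left_clip:
        cig.append((_OP_CODE["S"], left_clip))
    for op, ln, _ in core:
        cig.append((_OP_CODE[op], ln))
    if right_clip:
        cig.append((_OP_CODE["S"], right_clip))
    return ref_start, cig


def simulate_reads(
    truth: LocusTruth,
    mode: str,
    coverage: float = 40.0,
    read_length: int = 150,
    fragment_mean: float = 400.0,
    fragment_sd: float = 60.0,
    error_rate: float = 0.0,
    nmd_retention: float = 0.05,
    seed: int = 0,
) -> ReadSet:
    """Draw paired-end reads from the two haplotypes with truth alignments.

    ``mode`` is "dna" (fragments uniform over each haplotype's genome, equal
    haplotype probability) or "rna" (fragments from spliced transcripts, with
    any PTC-bearing transcript down-weighted to relative abundance
    ``nmd_retention``).
    """
    if mode not in ("dna", "rna"):
        raise ValueError("mode must be 'dna' or 'rna'")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if mode == "rna" and not (0.0 <= nmd_retention <= 1.0):
        raise ValueError("nmd_retention must lie in [0, 1]")
    if fragment_mean < read_length:
        raise ValueError("mean fragment length shorter than the read length")

    rng = np.random.default_rng(seed)
    if mode == "dna":
        templates = [truth.hap_genome(i) for i in range(2)]
        blocks = [truth.genome_blocks(i) for i in range(2)]
        abundance = np.array([1.0, 1.0])
        ref_template_len = len(truth.reference_seq)
    else:
        templates = [truth.hap_mrna(i) for i in range(2)]
        blocks = [truth.mrna_blocks(i) for i in range(2)]
        abundance = np.array(
            [nmd_retention if truth.is_nmd_target(i) else 1.0 for i in range(2)]
        )
        if abundance.sum() == 0:
            raise ValueError("both transcripts fully degraded; nothing to sequence")
        ref_template_len = truth.cds_length
    # fragments are drawn from the total nucleic-acid mass: a template's
    # fragment share is abundance x length, giving equal per-base coverage
    # per unit abundance (this is what makes the clipped fraction 0.5 for a
    # heterozygous insertion and the RNA allele bias 1/(1+nmd_retention))
    w = abundance * np.array([len(t) for t in templates], dtype=float)
    weights = w / w.sum()

    n_pairs = round(coverage * ref_template_len / (2 * read_length))
    reads: list[SimulatedRead] = []
    for k in range(n_pairs):
        h = int(rng.choice(2, p=weights))
        tmpl = templates[h]
        frag_len = int(round(rng.normal(fragment_mean, fragment_sd)))
        frag_len = max(read_length, min(frag_len, len(tmpl)))
        start = int(rng.integers(0, len(tmpl) - frag_len + 1))
        name = f"{truth.name}:{mode}:{k}"
        for mate, (qs, reverse) in enumerate(
            [(start, False), (start + frag_len - read_length, True)], start=1
        ):
            template_seq = mutate(tmpl[qs : qs + read_length], error_rate, rng)
            ref_start, cig = _truth_alignment(blocks[h], qs, read_length)
            reads.append(
                SimulatedRead(
                    query_name=name,
                    mate=mate,
                    fastq_sequence=revcomp(template_seq) if reverse else template_seq,
                    query_sequence=template_seq,
                    origin_haplotype=h,
                    origin_hap_name=truth.haplotypes[h].name,
                    origin_start=qs,
                    is_reverse=reverse,
                    reference_start=ref_start,
                    cigartuples=cig,
                )
            )
    return ReadSet(reads=reads, mode=mode, truth=truth, read_length=read_length, seed=seed)
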