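"""In-silico PCR: amplicon prediction and band-pattern genotyping.

An allele-specific diagnostic for a large insertion uses primers whose
binding sites exist only on one allele: a wild-type forward primer spans
the uninterrupted breakpoint (destroyed by the insertion), and an
insertion-specific forward primer spans the insert/flank junction (absent
without the insertion).  Site matching is purely sequence-based (a
mismatch budget plus an exactly matching 3' anchor; no melting-temperature
model), and genotype calls are made from the presence of expected product
sizes per reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .synthetic_data import LocusTruth
from .util import revcomp

DEFAULT_MAX_AMPLICON = 5000
DEFAULT_TOLERANCE = 5

PRESENT = "present"
ABSENT = "absent"
INVALID = "invalid"


@dataclass(frozen=True)
class Primer:
    """A PCR primer written 5'->3'.

    ``three_prime_anchor`` bases at the 3' end must match exactly;
    ``allowed_mismatches`` applies to the rest of the primer.
    """

    name: str
    sequence: str
    allowed_mismatches: int = 0
    three_prime_anchor: int = 3

    def __post_init__(self) -> None:
        if self.three_prime_anchor > len(self.sequence):
            raise ValueError("3' anchor longer than the primer")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("primer sequence must be over A/C/G/T")


@dataclass(frozen=True)
class Amplicon:
    template: str
    forward: str
    reverse: str
    start: int  # 0-based half-open on the template, inclusive of both primers
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _site_matches(template: str, site_seq: str, exact: Sequence[int], budget: int) -> list[int]:
    """Start offsets where `site_seq` occurs with <= budget mismatches,
    requiring exact identity at the offsets in `exact`."""
    import numpy as np

    n, k = len(template), len(site_seq)
    if n < k:
        return []
    tarr = np.frombuffer(template.encode(), dtype="S1")
    sarr = np.frombuffer(site_seq.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(tarr, k)
    mismatch = windows != sarr
    ok = mismatch.sum(axis=1) <= budget
    if len(exact):
        ok &= ~mismatch[:, list(exact)].any(axis=1)
    return np.nonzero(ok)[0].tolist()


def forward_sites(template: str, primer: Primer) -> list[int]:
    """Plus-strand binding-site start offsets of a forward primer."""
    k = len(primer.sequence)
    exact = range(k - primer.three_prime_anchor, k)
    return _site_matches(template, primer.sequence, list(exact), primer.allowed_mismatches)


def reverse_sites(template: str, primer: Primer) -> list[int]:
    """Plus-strand start offsets of a reverse primer's binding site.

    The site is the reverse complement of the primer; the primer's 3' end
    maps to the site's leftmost base.
    """
    site = revcomp(primer.sequence)
    exact = range(primer.three_prime_anchor)
    return _site_matches(template, site, list(exact), primer.allowed_mismatches)


def amplify(
    templates: Mapping[str, str],
    pairs: Sequence[tuple[Primer, Primer]],
    max_amplicon: int = DEFAULT_MAX_AMPLICON,
) -> list[Amplicon]:
    """All products of the primer pairs on each template, 5' end of the
    forward site through the distal end of the reverse site."""
    if not templates or not pairs:
        raise ValueError("amplify needs templates and primer pairs")
    out: list[Amplicon] = []
    for tname, seq in templates.items():
        for fwd, rev in pairs:
            fsites = forward_sites(seq, fwd)
            rsites = reverse_sites(seq, rev)
            for i in fsites:
                for j in rsites:
                    if j < i + len(fwd.sequence):
                        continue
                    end = j + len(rev.sequence)
                    if end - i <= max_amplicon:
                        out.append(Amplicon(tname, fwd.name, rev.name, i, end))
    return out


@dataclass
class DiagnosticScheme:
    """Expected product sizes per reaction and allele class.

    ``reactions`` maps a reaction name ("MT_F2+R1") to (allele_class,
    expected_length) with allele_class "mule" (insertion allele) or "wt".
    """

    reactions: dict[str, tuple[str, int]]
    tolerance: int = DEFAULT_TOLERANCE
    pairs: list[tuple[Primer, Primer]] = field(default_factory=list)


def call_genotype(
    bands: Mapping[str, Sequence[float] | float], scheme: DiagnosticScheme
) -> str:
    """MULE presence call from observed band lengths per reaction.

    "present" when any insertion-specific reaction shows its expected band;
    "absent" when only wild-type-specific reactions do; "invalid" when no
    control band appears at all.
    """
    seen = {"mule": False, "wt": False}
    for reaction, (allele_class, expected) in scheme.reactions.items():
        obs = bands.get(reaction, [])
        if isinstance(obs, (int, float)):
            obs = [obs]
        if any(abs(b - expected) <= scheme.tolerance for b in obs):
            seen[allele_class] = True
    if seen["mule"]:
        return PRESENT
    if seen["wt"]:
        return ABSENT
    return INVALID


def bands_from_amplicons(amplicons: Sequence[Amplicon]) -> dict[str, list[int]]:
    """Observed band lengths keyed by reaction name (forward+reverse)."""
    bands: dict[str, list[int]] = {}
    for a in amplicons:
        bands.setdefault(f"{a.forward}+{a.reverse}", []).append(a.length)
    return bands


def design_diagnostic(
    truth: LocusTruth,
    primer_length: int = 20,
    sizes: tuple[int, int, int] = (326, 276, 327),
) -> DiagnosticScheme:
    """Derive an allele-specific diagnostic from a locus carrying the insert.

    Mirrors the published scheme's geometry and product sizes: MT_F2 spans
    the insert's 3' junction (insertion allele only), WT_F1 spans the
    uninterrupted breakpoint (wild-type allele only), and the generic
    reverse primers R1/R2 sit in shared downstream flank, giving products
    of ``sizes`` = (MT_F2+R1, MT_F2+R2, WT_F1+R1).
    """
    if truth.insertion is None:
        raise ValueError("diagnostic design needs a locus with the insertion")
    b, te = truth.insertion
    L = len(te)
    ref = truth.reference_seq
    size_mt_r1, size_mt_r2, size_wt_r1 = sizes
    half = primer_length // 2
    m_hap = next(i for i, h in enumerate(truth.haplotypes) if h.insertion is not None)
    hap_m = truth.hap_genome(m_hap)

    wt_f1 = Primer("WT_F1", ref[b - half : b - half + primer_length])
    r1_end = (b - half) + size_wt_r1  # genomic end of the WT_F1+R1 product
    r1 = Primer("R1", revcomp(ref[r1_end - primer_length : r1_end]))
    # MT_F2 spans the insert 3' end / right-flank junction on the M haplotype
    mt_start = (b + L + (r1_end - b)) - size_mt_r1
    mt_f2 = Primer("MT_F2", hap_m[mt_start : mt_start + primer_length])
    r2_end_genomic = (mt_start + size_mt_r2) - L  # back to reference coordinates
    r2 = Primer("R2", revcomp(ref[r2_end_genomic - primer_length : r2_end_genomic]))

    pairs = [(mt_f2, r1), (mt_f2, r2), (wt_f1, r1)]
    reactions = {
        "MT_F2+R1": ("mule", size_mt_r1),
        "MT_F2+R2": ("mule", size_mt_r2),
        "WT_F1+R1": ("wt", size_wt_r1),
    }
    return DiagnosticScheme(reactions=reactions, pairs=pairs)


def run_diagnostic(
    templates: Mapping[str, str],
    scheme: DiagnosticScheme,
    max_amplicon: int = DEFAULT_MAX_AMPLICON,
) -> tuple[str, dict[str, list[int]]]:
    """Amplify a clone's haplotype templates and call MULE presence."""
    amps = amplify(templates, scheme.pairs, max_amplicon)
    bands = bands_from_amplicons(amps)
    return call_genotype(bands, scheme), bands
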