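"""Mendelian model of sodium-channel haplotypes with a silencing modifier.

The haplotype alphabet follows the field's shorthand: S is the wild-type,
expressed, insecticide-susceptible allele; R the expressed allele carrying
the kdr + skdr resistance mutations; M the wild-type allele silenced by the
transposon insertion (unexpressed, and — because the channel is essential —
homozygous-lethal).  Resistance is recessive: a genotype is resistant only
when every *expressed* haplotype carries the resistance mutations, which is
how the silencing of S by the insertion unmasks R in M/R heterozygotes.
Crosses enumerate the four equiprobable gamete pairs of a single autosomal
locus; clonal (parthenogenetic) propagation is simply the identity cross.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import pandas as pd


@dataclass(frozen=True)
class Haplotype:
    name: str
    expressed: bool
    resistance_conferring: bool
    note: str = ""


#: canonical alphabet; R_L carries the alternative skdr substitution (M918L)
#: whose resistance is inferred from monoallelic expression, not bioassayed
STANDARD_HAPLOTYPES: dict[str, Haplotype] = {
    "S": Haplotype("S", expressed=True, resistance_conferring=False),
    "R": Haplotype("R", expressed=True, resistance_conferring=True),
    "M": Haplotype("M", expressed=False, resistance_conferring=False),
    "R_L": Haplotype(
        "R_L", expressed=True, resistance_conferring=True,
        note="inferred resistant (M918L), not bioassayed",
    ),
}

RESISTANT = "resistant"
SUSCEPTIBLE = "susceptible"
NONVIABLE = "nonviable"


@dataclass(frozen=True)
class Genotype:
    """Unordered haplotype pair."""

    a: Haplotype
    b: Haplotype

    @classmethod
    def parse(cls, text: str, alphabet: Mapping[str, Haplotype] | None = None) -> "Genotype":
        """Parse "M/R"-style notation against the standard alphabet."""
        alphabet = alphabet or STANDARD_HAPLOTYPES
        names = text.split("/")
        if len(names) != 2:
            raise ValueError(f"genotype {text!r} is not of the form X/Y")
        try:
            return cls(alphabet[names[0]], alphabet[names[1]])
        except KeyError as exc:
            raise ValueError(f"unknown haplotype name: {exc.args[0]!r}") from exc

    @property
    def name(self) -> str:
        return "/".join(sorted((self.a.name, self.b.name)))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def phenotype(genotype: Genotype) -> str:
    """resistant / susceptible / nonviable under recessive resistance with
    an unexpressed, homozygous-lethal silenced allele."""
    expressed = [h for h in (genotype.a, genotype.b) if h.expressed]
    if not expressed:
        return NONVIABLE
    if all(h.resistance_conferring for h in expressed):
        return RESISTANT
    return SUSCEPTIBLE


@dataclass
class CrossResult:
    """Progeny distribution of a single-locus cross."""

    progeny: dict[str, Fraction]  # genotype name -> probability
    phenotypes: dict[str, Fraction]  # phenotype -> probability

    def percent(self, label: str) -> float:
        return 100.0 * float(self.phenotypes.get(label, Fraction(0)))

    @property
    def percent_resistant(self) -> float:
        return self.percent(RESISTANT)

    @property
    def percent_susceptible(self) -> float:
        return self.percent(SUSCEPTIBLE)

    @property
    def percent_nonviable(self) -> float:
        return self.percent(NONVIABLE)

    @property
    def percent_resistant_among_viable(self) -> float:
        viable = 1 - self.phenotypes.get(NONVIABLE, Fraction(0))
        if viable == 0:
            return float("nan")
        return 100.0 * float(self.phenotypes.get(RESISTANT, Fraction(0)) / viable)


def cross(parent1: Genotype, parent2: Genotype) -> CrossResult:
    """Enumerate the four equiprobable gamete pairs of two viable parents."""
    for p in (parent1, parent2):
        if phenotype(p) == NONVIABLE:
            raise ValueError(f"parent {p.name} is nonviable")
    geno: Counter = Counter()
    pheno: Counter = Counter()
    quarter = Fraction(1, 4)
    for g1 in (parent1.a, parent1.b):
        for g2 in (parent2.a, parent2.b):
            child = Genotype(g1, g2)
            geno[child.name] += quarter
            pheno[phenotype(child)] += quarter
    return CrossResult(progeny=dict(geno), phenotypes=dict(pheno))


@dataclass
class ScreenSummary:
    """Prevalence of the insertion allele in a field screen."""

    n_clones: int
    n_with_insertion: int
    prevalence_percent: float
    by_skdr_variant: dict[str, int]
    n_excluded: int = 0
    empty: bool = False


def screen_summary(table: pd.DataFrame) -> ScreenSummary:
    """Summarise a genotype table (columns: clone, mule_presence, skdr).

    ``mule_presence`` is boolean-like; ``skdr`` labels the co-occurring
    resistance variant (e.g. M918T or M918L) and stratifies the carriers.
    Malformed rows are excluded with a count.  Percentages use one-decimal
    rounding; an empty table reports 0 with a flag.
    """
    required = {"clone", "mule_presence"}
    if not required <= set(table.columns):
        raise ValueError(f"genotype table must have columns {sorted(required)}")
    ok = table["clone"].notna() & table["mule_presence"].notna()
    excluded = int((~ok).sum())
    rows = table[ok]
    n = len(rows)
    if n == 0:
        return ScreenSummary(0, 0, 0.0, {}, n_excluded=excluded, empty=True)
    present = rows["mule_presence"].astype(bool)
    carriers = rows[present]
    strat: dict[str, int] = {}
    if "skdr" in rows.columns:
        strat = carriers["skdr"].value_counts().to_dict()
    prevalence = round(100.0 * len(carriers) / n, 1)
    return ScreenSummary(
        n_clones=n,
        n_with_insertion=len(carriers),
        prevalence_percent=prevalence,
        by_skdr_variant=strat,
        n_excluded=excluded,
    )
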