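"""Mendelian consequences of the silenced allele, and field prevalence.

S = wild-type expressed allele, R = kdr+skdr resistance allele (recessive),
M = wild-type allele silenced by the insertion (unexpressed; two copies are
lethal because the channel is essential).  Crosses enumerate the four
equiprobable gamete pairs.
"""

import pandas as pd

from mule_unmask import Genotype, cross, phenotype, screen_summary

for g in ["S/S", "S/R", "R/R", "M/R", "M/M"]:
    print(f"genotype {g}: {phenotype(Genotype.parse(g))}")

print()
for p1, p2 in [("M/R", "S/R"), ("M/R", "R/R"), ("S/R", "S/R"), ("M/R", "M/R")]:
    r = cross(Genotype.parse(p1), Genotype.parse(p2))
    print(f"{p1} x {p2}: {r.percent_resistant:g}% resistant, "
          f"{r.percent_nonviable:g}% nonviable")
print("Silencing the susceptible allele doubles (50%) or quadruples (100%) "
      "the resistant progeny relative to a cross of plain heterozygotes (25%).")

rows = [{"clone": f"c{i}", "mule_presence": i < 8,
         "skdr": "M918T" if i < 2 else ("M918L" if i < 8 else "none")}
        for i in range(148)]
s = screen_summary(pd.DataFrame(rows))
print(f"\nfield screen: {s.n_with_insertion}/{s.n_clones} clones "
      f"({s.prevalence_percent}%) carry the insertion; "
      f"by skdr variant: {s.by_skdr_variant}")
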