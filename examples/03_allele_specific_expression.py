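"""Quantify allele-specific expression under nonsense-mediated decay.

RNA reads are drawn from the two spliced transcripts with the PTC-bearing
(insertion) transcript degraded to 5% residual abundance.  At each variant
site the fraction of reads carrying the resistance (alt) allele is tallied
and tested against the balanced 50:50 expectation.
"""

from mule_unmask import (
    LocusConfig, build_locus, classify_expression, count_alleles, simulate_reads,
)

for archetype, note in [
    ("62H2", "insertion silences the wild-type allele"),
    ("4H", "no insertion: both alleles expressed"),
]:
    truth = build_locus(LocusConfig(archetype=archetype, seed=1))
    rna = simulate_reads(truth, "rna", coverage=150, nmd_retention=0.05, seed=3)
    counts = count_alleles(rna.sorted_alignments(), truth.sites)
    verdict = classify_expression(counts)
    print(f"{archetype} ({note}):")
    for c in counts:
        print(f"  {c.site.label}: {c.alt_count} alt / {c.ref_count} ref reads "
              f"-> {100 * c.alt_fraction:.1f}% alt, p={c.binomial_p:.2g}, "
              f"{c.classification}")
    print(f"  gene verdict: {verdict}")
print("With 5% NMD retention the expected alt fraction is 1/1.05 = 95.2%, "
      "inside the 90-97% band observed for silenced clones; the balanced "
      "heterozygote sits near 50%.")
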