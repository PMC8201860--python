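# Methods

This note documents the models, conventions and numerical choices behind
`mule_unmask`, in the order data flows through the package.

## The simulated locus

The generator emulates the genetic situation of pyrethroid-resistant aphid
clones in which a transposon insertion unmasks recessive resistance.  The
default locus is an 8,000-nt single-copy gene with a 4,800-nt CDS spread
over three exons (500–2,000, 2,600–4,400, 5,000–6,500).  The CDS is random
sense codons between an ATG and a TAA, so the wild-type transcript carries
no internal stop.  Three haplotypes are defined on it:

- **S** — the reference (wild-type, expressed, susceptible) sequence;
- **R** — S plus the two linked resistance substitutions (skdr/kdr
  analogues), placed 346 and 634 nt downstream of the insertion breakpoint
  inside the same exon, mirroring the study geometry; alternate bases are
  chosen so the changed codon is never a stop;
- **M** — S plus a DNA-transposon insertion at CDS nt 2,360 (0-based
  genomic breakpoint 3,459), i.e. codon ceil(2360/3) = 787.

Clone archetypes map to haplotype pairs: `1X` = S/S, `4H` = S/R,
`62H2`/`88H2` = M/R, `92H6` = R/R.  The insertion and the resistance
alleles never co-occur on a haplotype, as observed in the resistant clones.

**Breakpoint convention.**  An insertion is stored as a 0-based position
*b*: the element lies immediately before reference offset *b*.  Reports
print the equivalent 1-based "after nucleotide *b*" form (numerically the
same integer).  This round-trips cleanly with half-open CDS intervals.

**The element.**  `make_te` builds a random element whose last `t` bases
are the reverse complement of its first `t` bases except at exactly `m`
alignment columns (imperfect TIRs).  Planted mismatches are spaced at least
5 columns apart, kept off the TIR's inner edge, and the two columns just
inside the element are forced non-complementary.  These are generator
guarantees that the planted repeat is unambiguously the maximal terminal
repeat — without them no finder could recover the planted length exactly,
because chance complementarity just inside the element extends any
qualifying repeat.  The default locus element is the 5'-truncated suffix
(2,076 nt of a 2,576-nt parent with 109-nt TIRs, 5 mismatches); the intact
parent is kept as the annotation library, so the truncated copy itself has
no TIR pair — as for a genuine 5'-truncated element — and annotation
recovers `(5p, 500)`.

## Read simulation and truth alignments

Paired 150-nt reads are drawn from normal fragments (mean 400 nt, sd 60 —
ordinary short-insert library geometry; no quality model beyond constant
Q40, no duplicates or GC bias).  The number of pairs is
`round(coverage · template_length / (2 · read_length))`, with the template
being the locus (DNA) or the spliced reference transcript (RNA).  A
fragment's template is chosen with probability proportional to *abundance ×
template length* — uniform sampling from total nucleic-acid mass.  DNA
abundances are equal; RNA abundances down-weight any PTC-bearing transcript
to `nmd_retention` (default 0.05, the midpoint of the observed 3–10%
residual expression).  The length weighting is what makes the breakpoint
clipped-read fraction exactly 0.5 in a heterozygote and the RNA
alternate-allele fraction exactly `1/(1+retention)`, since the insertion
lengthens one template.

The NMD rule is deliberately minimal: a transcript is a decay target iff
its translation from the start codon hits a stop before the native final
codon.  No exon-junction-distance refinement is modelled.

Truth alignments are computed analytically from each read's origin by
walking a block map of the haplotype (or transcript) against the reference:
intron jumps become `N`, bases inside the inserted element become soft
clips.  A read spanning a short insert entirely keeps its longer flanking
match and clips the rest, which is how an aligner would report it.  Errors
are uniform substitutions only (default 0; 0.005 in the error-tolerance
tests) — enough to stress every consensus step without complicating the
truth CIGARs.  Identical seeds give byte-identical FASTQ/SAM output; there
is no hidden global RNG.

## Breakpoint detection

Soft-clipped read ends are collected per side (tail-clipped right = insert
5' evidence; head-clipped left = insert 3' evidence), keeping a read only
if both its clip and its matched anchor reach `min_clip_length` (20 nt —
shorter tails are alignment noise).  Positions within a 5-nt merge window
collapse into one cluster whose consensus is the per-column majority over
breakpoint-anchored tails, masking columns under 60% agreement as N.  A
right and a left cluster within the merge window pair into a call; the two
tail consensi are *not* required to overlap each other — for inserts longer
than the read they sample opposite ends of the element.

**Allele fraction.**  A long insertion presents two junctions, so the
insertion-supporting count entering the allele fraction is the mean of the
two per-side supports, compared against unclipped reads whose matched block
covers the breakpoint by ≥ `min_clip_length` on both sides.  Clipped and
spanning evidence then occupy equal-width windows (read_length − 2·20) and
the fraction is an unbiased estimate of the insertion allele dosage; 0.2 ≤
fraction ≤ 0.8 calls a heterozygote.  Calls with fewer than 3 supporting
reads per junction are suppressed.

## Insert assembly

Reconstruction follows the iterative-extension idea: the right-cluster tail
consensus (insert 5' end) seeds a rightward contig, the left-cluster
consensus a leftward one, and each round recruits reads — used unoriented —
whose terminal `k_overlap` = 31 bases match the contig end with ≤ 1
substitution.  Three stringency rules guard against chimerism:

1. **Whole-overlap verification.**  A recruited read must match the contig
   (plus the known reference flank behind the breakpoint-anchored seed)
   over its entire overlap, not just the terminal window.  The flank
   context matters at early rounds, when the contig is shorter than a read,
   and rejects reverse-complement impostors from the element's own TIRs.
2. **Quorum with a long-overlap rescue.**  Extension columns need 3
   agreeing reads; below that quorum a column extends only if all
   contributing reads agree unanimously and carry verified overlaps ≥ 50 nt
   (counting previously accepted columns).  Pure quorum stalls on Poisson
   coverage dips that occur regularly at 30–40×; pure single-read extension
   would invite errors.  The rescue takes the evidence a long verified
   overlap actually provides.
3. **Tie abort.**  An exact consensus tie stops extension — truncation is
   preferred over guessing between divergent read populations.

Extension stops on reaching `max_rounds` (flagged incomplete), stalling, or
walking 50 consecutive bases into the reference flank beyond the breakpoint
(the insert has been crossed).  Merging then tries, in order: a seed-to-seed
overlap (short inserts merge at round 0), suffix/prefix overlaps ≥ 40 nt
with ≤ 1 mismatch in both arrangements, containment of one contig in the
other, and finally a single flank-reaching contig spanning the insert
alone.  Flank trimming against the reference applies only to
extension-grown contig ends: a seed-anchored end *is* the insert boundary,
and greedy trimming there could shave true insert bases that happen to
match the flank.  If nothing merges the result is returned "unmerged" with
both contigs — reported, not guessed.

Before trimming, the merged contig is **polished**: every read is re-placed
on it by exact 24-mer anchors with whole-read verification at ≤ 2
mismatches (full containment required), and each column takes the
full-depth majority, ties keeping the existing base.  Extension-time
consensus sees only the reads recruited in one round's window, so a column
passed during a coverage dip can carry a single read's error; the pileup
restores true local depth.  The strict placement threshold keeps
cross-TIR reverse-complement placements (≈ 5 mismatches) out of the vote.

No target-site duplication is modelled or resolved; a TSD would surface as
duplicated flank bases in the reconstruction and is left to the reader.
The assembler is not a general-purpose tool: one targeted insertion per
call, with repeat resolution limited to the stringent-overlap rule — a real
limitation for high-copy elements in real genomes.

## TIR detection and library comparison

TIR search is anchored at the element termini (left repeat starts at 0,
right repeat ends at the last base) and considers substitutions only, which
keeps an exact brute-force oracle feasible.  Among candidate lengths from
`min_length` (15) to `search_window` (300) whose mismatch fraction is ≤ 0.1,
the reported hit maximises an alignment score (+1 match, −3 mismatch; ties
to the longer length).  The score objective — rather than "longest length
under the cap" — is what makes planted-repeat recovery exact: with a slack
10% budget, the longest qualifying length systematically overshoots a
planted repeat through chance complementarity.

Library comparison aligns the shorter sequence within the longer with
edlib (infix mode; plain global alignment for equal lengths, keeping
identity symmetric) and reports identity relative to the shorter.  If the
best match is a longer entry and the element aligns flush to its end
(± 5 nt) but not its start, the element is 5'-truncated with
`bases_missing` equal to the unaligned prefix; symmetrically for 3'.
Homology-based classification (transposase domains, families, phylogeny)
is out of scope; the annotation is purely structural.

## Frame impact and NMD

`apply_insertion` splices an insert before 1-based CDS position *p*;
`annotate_impact` translates the modified CDS from codon 1 under the
standard code.  The first disrupted codon is `ceil(p/3)`; the first stop is
premature unless it coincides with the native stop, which stays in frame
only when the insert length is a multiple of three (or the insert was
appended after the native stop).  `nmd_target` is true iff a premature stop
precedes the native stop — the same rule the simulator uses, keeping the
two modules consistent by construction.  Ambiguity codes translate to X and
never count as stops.

## Allele-specific expression

Reads are tallied per variant site by walking each alignment's CIGAR
(spliced `N` blocks honoured; deletions and clipped positions excluded;
base quality ≥ 20; duplicate read names per site counted once, so
overlapping mates contribute one observation).  A site with ≥ 20
informative reads is `monoallelic_alt` when the alternate fraction is
≥ 0.85 *and* an exact two-sided binomial test against 0.5 gives p < 0.01
(threshold below the observed 0.90 floor but far above heterozygous
expectation; the formal test is this package's operationalisation — the
original evidence was descriptive).  The gene verdict requires all
informative sites to agree in direction; monoallelic sites in opposite
directions flag "discordant".  No mapping-bias correction is applied:
simulated reads are symmetric.  On real data, reference-mapping bias
deflates the alternate fraction and would need a correction step.

## Cross model

Haplotypes carry two booleans: `expressed` and `resistance_conferring`
(S: expressed, not conferring; R: both; M: neither — the silenced wild-type
allele).  A genotype is nonviable iff neither haplotype is expressed
(the channel is essential), resistant iff viable and every *expressed*
haplotype confers resistance (recessivity), susceptible otherwise.
Crosses enumerate the four equiprobable gamete pairs with exact `Fraction`
arithmetic; the model is autosomal and single-locus, with no recombination
(nothing to recombine) and no modelling of the aphid's cyclical
parthenogenesis — clonal propagation is the identity cross.  An `R_L`
haplotype (the alternative skdr substitution M918L) is predefined as
resistance-conferring but flagged inferred-not-bioassayed.  Temperature-
dependent fitness costs of M carriers are outside the phenotype rule,
which covers insecticide response only.

## In-silico PCR

Primer sites are matched purely by sequence: a mismatch budget (default 0)
over the primer with an exactly matching 3' anchor (default 3 nt); reverse
primers bind as their reverse complement with the anchor at the site's
leftmost base.  Amplicons run from the 5' end of the forward site to the
distal end of the reverse site, capped at 5,000 nt.  No thermodynamics
(melting temperature, dimers, secondary structure) — a documented
limitation.  `design_diagnostic` derives the published scheme's geometry on
the simulated locus: the insertion-specific forward primer spans the
element's 3' junction, the wild-type primer spans the uninterrupted
breakpoint, and the two shared reverse primers sit in downstream flank,
yielding 326/276-nt insertion products and a 327-nt wild-type control.
Band-pattern genotyping (± 5 nt size tolerance) calls presence when any
insertion-specific band appears, absence when only wild-type bands do, and
invalid otherwise.

## Dose-response and expression statistics

Probit regression is a binomial GLM with probit link on log10 dose (the
POLO convention), fitted by IRLS via statsmodels; LC50 = 10^(−b₀/b₁).  The
95% CI uses Fieller's theorem on −b₀/b₁, falling back to the delta method
(flagged) when the Fieller discriminant is unusable.  All-dead or all-alive
data return a flagged fit instead of an estimate.  No natural-mortality
(Abbott) correction and no heterogeneity-factor scaling of standard errors
are applied — the simulations contain neither.  Resistance ratios are
returned at full precision; the bioassay table formats them to 3
significant figures.  The equality LRT compares k separate probit fits
against one pooled fit: χ² = 2(Σℓ_separate − ℓ_pooled) on 2(k−1) degrees of
freedom.  Delta-delta-Ct fold changes normalise each target Ct by the
arithmetic mean of the housekeeping Cts — identical to dividing the linear
quantity by their geometric mean — and calibrate to a named sample.

## Problem sizes and what passing tests show

The suite runs error-free recovery at 30–40× on 5–8 kb loci (insert
lengths 80–2,076 nt, 20 seeds each), 50 positive and 50 negative detection
simulations, 200 allele-bias replicates at 100×, 100 planted-TIR fixtures,
and probit calibration over several hundred fits with 1,000 null LRT
simulations — sizes at which each stochastic check has comfortable margin
while the whole suite stays fast.  Fixed seeds make every stochastic test
reproducible.

The generator emulates the *structure* of the real evidence — clip
signatures, NMD-skewed allele counts, junction-specific primer sites — not
the messiness of real data: no mapping ambiguity from a full genome's
repeat content, no indel or quality-dependent error model, no PCR
duplicates, no reference-mapping bias, one element copy rather than a
family.  Passing tests therefore demonstrate that the algorithms are
correct on their stated evidence model, not that they are robust to every
artefact of a production resequencing experiment.
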