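"""Shared simulation fixtures.

Heavy ground-truth objects are session-scoped: the canonical insertion-
carrying clone (62H2-like), its DNA/RNA read sets, and the breakpoint call
derived from them.
"""

from __future__ import annotations

import pytest

from mule_unmask import (
    LocusConfig,
    ReadPool,
    build_locus,
    detect_insertions,
    simulate_reads,
)

# compact single-exon locus used where geometry need not mirror the study gene
COMPACT = dict(
    locus_length=5000,
    cds_intervals=((400, 4600),),
    breakpoint_cds_position=2000,
    site_offsets=(346, 634),
)


@pytest.fixture(scope="session")
def truth62():
    """Insertion-bearing heterozygote on the default study-geometry locus."""
    return build_locus(LocusConfig(archetype="62H2", seed=1))


@pytest.fixture(scope="session")
def dna62(truth62):
    return simulate_reads(truth62, "dna", coverage=40, seed=101)


@pytest.fixture(scope="session")
def calls62(dna62):
    return detect_insertions(dna62.sorted_alignments())


@pytest.fixture(scope="session")
def pool62(dna62):
    return ReadPool(dna62.sequences())


@pytest.fixture(scope="session")
def rna62(truth62):
    return simulate_reads(
        truth62, "rna", coverage=150, nmd_retention=0.05, seed=102
    )


@pytest.fixture(scope="session")
def truth1x():
    return build_locus(LocusConfig(archetype="1X", seed=1))


@pytest.fixture(scope="session")
def dna1x(truth1x):
    return simulate_reads(truth1x, "dna", coverage=40, seed=103)


@pytest.fixture(scope="session")
def truth4h():
    return build_locus(LocusConfig(archetype="4H", seed=1))
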