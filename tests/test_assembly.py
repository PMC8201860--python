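"""Iterative extension and insert reconstruction against simulation truth."""

from __future__ import annotations

import math

import edlib
import pytest

from mule_unmask import (
    LocusConfig,
    ReadPool,
    assemble_insertion,
    build_locus,
    detect_insertions,
    iterative_extend,
    simulate_reads,
)
from mule_unmask.breakpoints import LEFT, RIGHT, ClipCluster, InsertionCall
from mule_unmask.util import revcomp
from tests.conftest import COMPACT


def _simulate_and_call(te_length, tir, mism, seed, coverage=30, error_rate=0.0):
    truth = build_locus(
        LocusConfig(
            archetype="62H2", seed=seed, te_length=te_length,
            te_tir_length=tir, te_tir_mismatches=mism, te_truncated_5p=0,
            **COMPACT,
        )
    )
    reads = simulate_reads(truth, "dna", coverage=coverage, seed=seed + 9001,
                           error_rate=error_rate)
    (call,) = detect_insertions(reads.sorted_alignments())
    return truth, reads, call


def test_full_insert_recovered_exactly(truth62, calls62, pool62):
    """The 2,076-nt element is reconstructed byte-for-byte at 40x."""
    result = assemble_insertion(calls62[0], pool62, truth62.reference_seq)
    assert result.status == "merged"
    assert result.length == 2076
    assert result.sequence == truth62.insertion[1].sequence


@pytest.mark.parametrize("te_length,tir", [(300, 50), (1000, 109)])
def test_exact_recovery_other_lengths(te_length, tir):
    truth, reads, call = _simulate_and_call(te_length, tir, 3, seed=11)
    result = assemble_insertion(call, ReadPool(reads.sequences()), truth.reference_seq)
    assert result.sequence == truth.insertion[1].sequence


def test_short_insert_merges_without_extension():
    """An insert shorter than the read length is spanned by the tails and
    merges immediately (round 0)."""
    truth, reads, call = _simulate_and_call(80, 10, 1, seed=13)
    result = assemble_insertion(call, ReadPool(reads.sequences()), truth.reference_seq)
    assert result.status == "merged"
    assert result.sequence == truth.insertion[1].sequence
    assert result.left_rounds == 0 and result.right_rounds == 0


def test_round_count_bounded():
    """Termination in ~insert_length/(read_length - k) rounds per side."""
    truth, reads, call = _simulate_and_call(1000, 109, 5, seed=17)
    result = assemble_insertion(call, ReadPool(reads.sequences()), truth.reference_seq)
    bound = math.ceil(1000 / (150 - 31)) + 2
    assert result.right_rounds <= bound and result.left_rounds <= bound


def test_sequencing_errors_tolerated():
    """0.5% substitution errors at 60x: >= 99.9% identity to truth."""
    for seed in range(4):
        truth, reads, call = _simulate_and_call(
            2076, 109, 5, seed=23 + seed, coverage=60, error_rate=0.005
        )
        result = assemble_insertion(call, ReadPool(reads.sequences()), truth.reference_seq)
        assert result.status == "merged"
        te = truth.insertion[1].sequence
        dist = edlib.align(result.sequence, te)["editDistance"]
        assert dist <= len(te) * 0.001


def test_no_overlapping_reads_returns_seed():
    seed = "ACGTACGTACGTACGTACGTACGTACGTACGTACG"
    pool = ReadPool(["T" * 100, "G" * 100])
    contig = iterative_extend(seed, pool, "rightward", k_overlap=20)
    assert contig.sequence == seed
    assert contig.rounds == 0 and contig.status == "stalled"


def test_exact_tie_stops_extension():
    """Two equally supported divergent read populations: extension refuses
    to guess and stops at the tie column."""
    import numpy as np

    from mule_unmask.util import random_seq

    rng = np.random.default_rng(42)
    seed = random_seq(40, rng)
    branch_a = seed + "A" + random_seq(60, rng)
    branch_c = seed + "C" + random_seq(60, rng)
    pool = ReadPool([branch_a] * 3 + [branch_c] * 3)
    contig = iterative_extend(seed, pool, "rightward", k_overlap=40)
    assert contig.sequence == seed
    assert contig.status == "stalled"


def test_reverse_complement_symmetry(truth62, calls62, dna62):
    """Assembling the mirrored locus with swapped cluster roles yields the
    reverse complement of the insert."""
    call = calls62[0]
    ref = truth62.reference_seq
    b = call.breakpoint
    rc_b = len(ref) - b
    rc = call.right_cluster
    lc = call.left_cluster
    swapped_right = ClipCluster(
        rc_b, RIGHT, lc.read_names, tail_consensus=revcomp(lc.tail_consensus),
        agreement=lc.agreement[::-1], coverage=lc.coverage[::-1],
    )
    swapped_left = ClipCluster(
        rc_b, LEFT, rc.read_names, tail_consensus=revcomp(rc.tail_consensus),
        agreement=rc.agreement[::-1], coverage=rc.coverage[::-1],
    )
    mirrored_call = InsertionCall(
        rc_b, swapped_left, swapped_right, call.clipped_support,
        call.spanning_unclipped, call.zygosity_call,
    )
    pool = ReadPool(dna62.sequences())  # reads are used unoriented
    result = assemble_insertion(mirrored_call, pool, revcomp(ref))
    assert result.sequence == revcomp(truth62.insertion[1].sequence)


def test_unmergeable_contigs_reported_not_guessed():
    """If reads only cover the insert ends, the two contigs cannot meet and
    the result is flagged unmerged with both contigs attached."""
    truth, reads, call = _simulate_and_call(2076, 109, 5, seed=31)
    te = truth.insertion[1].sequence
    # keep only reads that avoid the insert middle
    b = truth.insertion[0]
    mid_lo, mid_hi = b + 700, b + len(te) - 700
    kept = [
        r.fastq_sequence
        for r in reads.reads
        if not (
            r.origin_hap_name == "M"
            and r.origin_start + 150 > mid_lo
            and r.origin_start < mid_hi
        )
    ]
    result = assemble_insertion(call, ReadPool(kept), truth.reference_seq)
    assert result.status == "unmerged"
    assert result.contigs is not None and result.sequence == ""
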