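"""Generator ground truth: element construction, locus archetypes, read
conservation, truth alignments, allele balance and determinism."""

from __future__ import annotations

import pytest

from mule_unmask import (
    LocusConfig,
    LocusTruth,
    build_locus,
    make_te,
    simulate_reads,
)
from mule_unmask.io import write_fastq, write_sam
from mule_unmask.util import hamming, revcomp


class TestMakeTE:
    def test_perfect_tirs_by_direct_string_check(self):
        te = make_te(300, 50, 0, seed=7)
        assert len(te.sequence) == 300
        assert revcomp(te.sequence[250:300]) == te.sequence[0:50]

    def test_imperfect_tirs_have_exact_mismatch_count(self):
        te = make_te(2076, 109, 5, seed=1)
        assert len(te.sequence) == 2076
        aligned = revcomp(te.sequence[-109:])
        assert hamming(te.sequence[:109], aligned) == 5
        assert te.tir_length == 109 and te.tir_mismatches == 5

    def test_zero_tir_element(self):
        te = make_te(200, 0, 0, seed=1)
        assert te.tir_length == 0 and len(te.sequence) == 200

    @pytest.mark.parametrize(
        "args", [(100, 60, 0), (50, 10, 10), (200, 20, 10)]
    )
    def test_invalid_parameters_raise(self, args):
        with pytest.raises(ValueError):
            make_te(*args, seed=0)

    def test_deterministic_for_seed(self):
        assert make_te(500, 40, 3, seed=9).sequence == make_te(500, 40, 3, seed=9).sequence


class TestBuildLocus:
    def test_insertion_archetype_geometry(self, truth62):
        ins = truth62.insertion
        assert ins is not None
        b, te = ins
        assert truth62.insertion_cds_position == 2360
        assert len(te.sequence) == 2076
        # insertion on the wild-type background; resistance alleles in trans
        hap_m, hap_r = truth62.haplotypes
        assert hap_m.insertion is not None and not hap_m.variant_alleles
        assert hap_r.insertion is None
        assert set(hap_r.variant_alleles.values()) == {
            s.alt_base for s in truth62.sites
        }
        # both sites downstream of the breakpoint on the same exon
        for site, offset in zip(truth62.sites, (346, 634)):
            assert site.cds_position == 2360 + offset
            assert truth62.reference_seq[site.position] == site.ref_base

    def test_susceptible_archetype_identical_haplotypes(self, truth1x):
        assert truth1x.insertion is None
        assert truth1x.hap_genome(0) == truth1x.hap_genome(1) == truth1x.reference_seq

    def test_resistant_homozygote(self):
        truth = build_locus(LocusConfig(archetype="92H6", seed=2))
        for hap in truth.haplotypes:
            assert hap.insertion is None
            assert len(hap.variant_alleles) == 2

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError, match="archetype"):
            build_locus(LocusConfig(archetype="nope", seed=0))

    def test_breakpoint_outside_cds_rejected(self):
        with pytest.raises(ValueError):
            build_locus(
                LocusConfig(archetype="62H2", seed=0, breakpoint_cds_position=10_000)
            )

    def test_cds_splice_reproduces_mrna(self, truth62):
        # wild-type transcript is the spliced CDS; the inserted transcript
        # carries the element at the annotated CDS offset
        assert truth62.hap_mrna(1) == truth62.hap_cds(1)
        b, te = truth62.insertion
        off = truth62.insertion_cds_position - 1
        expected = (
            truth62.cds_seq[:off] + te.sequence + truth62.cds_seq[off:]
        )
        assert truth62.hap_mrna(0) == expected
        assert truth62.is_nmd_target(0) and not truth62.is_nmd_target(1)

    def test_json_roundtrip(self, truth62):
        clone = LocusTruth.from_json(truth62.to_json())
        assert clone.reference_seq == truth62.reference_seq
        assert clone.insertion[1].sequence == truth62.insertion[1].sequence
        assert clone.sites == truth62.sites


class TestSimulateReads:
    def test_read_pair_count_conservation(self, truth62, dna62):
        n_pairs = len(dna62.reads) / 2
        expected = 40 * len(truth62.reference_seq) / (2 * 150)
        assert abs(n_pairs - round(expected)) <= 1

    def test_truth_cigars_consume_read_length(self, dna62):
        for r in dna62.reads:
            if r.cigartuples is None:
                continue
            q = sum(ln for op, ln in r.cigartuples if op in (0, 1, 4))
            assert q == 150

    def test_clipped_tails_spell_insert_bases(self, truth62, dna62):
        """Error-free soft-clip tails must equal the haplotype bases they
        came from (insert-derived at the breakpoint)."""
        hap = truth62.hap_genome(0)
        checked = 0
        for r in dna62.reads:
            if r.cigartuples is None or r.origin_hap_name != "M":
                continue
            if r.cigartuples[-1][0] == 4:  # trailing clip
                ln = r.cigartuples[-1][1]
                assert r.query_sequence[-ln:] == hap[
                    r.origin_start + 150 - ln : r.origin_start + 150
                ]
                checked += 1
        assert checked > 5

    def test_dna_allele_balance(self, truth62):
        """Clipped fraction of breakpoint-spanning reads ~ 0.5 (het)."""
        b = truth62.insertion[0]
        clipped = spanning = 0
        for seed in range(30):
            rs = simulate_reads(truth62, "dna", coverage=40, seed=500 + seed)
            for r in rs.reads:
                if r.origin_hap_name == "M":
                    # spans the junction if it touches both sides
                    if r.origin_start < b and r.origin_start + 150 > b:
                        clipped += 1
                elif r.reference_start is not None:
                    if r.reference_start < b and r.reference_start + 150 > b:
                        spanning += 1
        n = clipped + spanning
        assert n >= 1000
        sd = (0.25 / n) ** 0.5
        assert abs(clipped / n - 0.5) < 3 * sd

    def test_rna_bias_matches_nmd_retention(self, truth62, rna62):
        """Alt fraction at each site ~ 1/(1 + nmd_retention)."""
        expected = 1 / 1.05
        for site in truth62.sites:
            ref = alt = 0
            for r in rna62.reads:
                if r.is_unmapped:
                    continue
                # truth-level count: origin haplotype determines the allele
                pos = r.reference_start
                covered = False
                for op, ln in r.cigartuples:
                    if op == 0 and pos <= site.position < pos + ln:
                        covered = True
                    if op in (0, 2, 3):
                        pos += ln
                if covered:
                    if r.origin_hap_name == "R":
                        alt += 1
                    else:
                        ref += 1
            n = ref + alt
            sd = (expected * (1 - expected) / n) ** 0.5
            assert abs(alt / n - expected) < 3 * sd

    def test_rna_mode_validates_retention(self, truth62):
        with pytest.raises(ValueError):
            simulate_reads(truth62, "rna", nmd_retention=1.5, seed=0)

    def test_fragment_shorter_than_read_rejected(self, truth62):
        with pytest.raises(ValueError):
            simulate_reads(truth62, "dna", fragment_mean=100, read_length=150, seed=0)

    def test_deterministic_output_bytes(self, truth62, tmp_path):
        """Identical seed and config give byte-identical FASTQ and SAM."""
        files = {}
        for tag in ("a", "b"):
            rs = simulate_reads(truth62, "dna", coverage=10, seed=77)
            write_fastq(rs, tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq")
            write_sam(rs, tmp_path / f"{tag}.sam")
            files[tag] = [
                (tmp_path / f"{tag}_1.fq").read_bytes(),
                (tmp_path / f"{tag}_2.fq").read_bytes(),
                (tmp_path / f"{tag}.sam").read_bytes(),
            ]
        assert files["a"] == files["b"]
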