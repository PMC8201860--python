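"""End-to-end orchestration: simulate -> detect -> assemble -> annotate ->
frame impact -> allele-specific expression -> genetic verdict.

Composes the evidence chain by which a heterozygous coding-sequence
transposon insertion is discovered from soft-clipped reads, reconstructed,
classified, and linked to monoallelic expression of the resistance allele
and the resulting phenotype.  Every stage runs on simulated data with a
known ground truth; the report records what each stage concluded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import ase as ase_mod
from . import breakpoints as bp_mod
from .assembly import ReadPool, assemble_insertion, write_insert_fasta
from .cross_model import Genotype, phenotype
from .frame_impact import annotate_impact
from .io import write_fasta, write_fastq, write_sam, write_truth_tsv
from .synthetic_data import LocusConfig, build_locus, simulate_reads
from .te_annotation import compare_to_library

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run; the seed is mandatory and every
    stage derives its randomness from it."""

    archetype: str = "62H2"
    seed: int = 0
    dna_coverage: float = 40.0
    rna_coverage: float = 60.0
    read_length: int = 150
    error_rate: float = 0.0
    nmd_retention: float = 0.05
    out_dir: str | None = None
    locus: dict = field(default_factory=dict)  # LocusConfig overrides
    detect: dict = field(default_factory=dict)
    assemble: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ValueError("config must set a seed")
        return cls(**d)


@dataclass
class RunReport:
    """Final verdict table of an end-to-end run."""

    archetype: str
    seed: int
    insertion_detected: bool = False
    breakpoint: int | None = None  # 0-based
    breakpoint_matches_truth: bool | None = None
    zygosity: str | None = None
    insertion_allele_fraction: float | None = None
    insert_length: int | None = None
    insert_matches_truth: bool | None = None
    tir_length: int | None = None
    best_library_match: str | None = None
    library_identity_percent: float | None = None
    truncation_end: str | None = None
    truncation_bases_missing: int | None = None
    insertion_cds_position: int | None = None
    first_disrupted_codon: int | None = None
    first_ptc_codon: int | None = None
    nmd_target: bool | None = None
    ase_alt_fractions: dict = field(default_factory=dict)
    ase_verdict: str | None = None
    genotype: str | None = None
    predicted_phenotype: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_end_to_end(config: RunConfig) -> RunReport:
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = RunReport(archetype=config.archetype, seed=config.seed)

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("simulate")
        truth = build_locus(
            LocusConfig(archetype=config.archetype, seed=config.seed, **config.locus)
        )
        dna = simulate_reads(
            truth, "dna", coverage=config.dna_coverage,
            read_length=config.read_length, error_rate=config.error_rate,
            seed=config.seed + 1,
        )
        rna = simulate_reads(
            truth, "rna", coverage=config.rna_coverage,
            read_length=config.read_length, error_rate=config.error_rate,
            nmd_retention=config.nmd_retention, seed=config.seed + 2,
        )
        if out is not None:
            write_fasta({truth.name: truth.reference_seq}, out / "locus.fa")
            (out / "locus.json").write_text(truth.to_json())
            write_sam(dna, out / "dna.sam")
            write_sam(rna, out / "rna.sam")
            write_fastq(dna, out / "dna_r1.fq", out / "dna_r2.fq")
            write_truth_tsv(dna, out / "dna_truth.tsv")
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    try:
        _stage("detect")
        calls = bp_mod.detect_insertions(dna.sorted_alignments(), **config.detect)
        if out is not None:
            bp_mod.write_calls_tsv(calls, out / "calls.tsv")
            bp_mod.write_calls_vcf(calls, truth.name, out / "calls.vcf")
    except Exception as exc:
        raise StageError("detect", exc) from exc

    truth_ins = truth.insertion
    if calls:
        call = max(calls, key=lambda c: c.clipped_support)
        report.insertion_detected = True
        report.breakpoint = call.breakpoint
        report.zygosity = call.zygosity_call
        report.insertion_allele_fraction = round(call.insertion_allele_fraction, 4)
        if truth_ins is not None:
            report.breakpoint_matches_truth = call.breakpoint == truth_ins[0]

        try:
            _stage("assemble")
            result = assemble_insertion(
                call, ReadPool(dna.sequences()), truth.reference_seq,
                **config.assemble,
            )
            if result.status == "merged":
                report.insert_length = result.length
                if truth_ins is not None:
                    report.insert_matches_truth = (
                        result.sequence == truth_ins[1].sequence
                    )
                if out is not None:
                    write_insert_fasta(result, out / "insert.fa")
        except Exception as exc:
            raise StageError("assemble", exc) from exc

        if report.insert_length:
            try:
                _stage("annotate")
                ann = compare_to_library(result.sequence, truth.te_library)
                report.tir_length = ann.tir.length if ann.tir else None
                report.best_library_match = ann.best_match
                if ann.library_matches:
                    report.library_identity_percent = round(ann.library_matches[0][1], 1)
                report.truncation_end = ann.truncation_end
                report.truncation_bases_missing = ann.bases_missing
            except Exception as exc:
                raise StageError("annotate", exc) from exc

            try:
                _stage("impact")
                cds_pos = truth._insertion_cds_offset(call.breakpoint) + 1
                impact = annotate_impact(truth.cds_seq, cds_pos, result.sequence)
                report.insertion_cds_position = cds_pos
                report.first_disrupted_codon = impact.first_disrupted_codon
                report.first_ptc_codon = impact.first_ptc_codon
                report.nmd_target = impact.nmd_target
            except Exception as exc:
                raise StageError("impact", exc) from exc

    try:
        _stage("ase")
        counts = ase_mod.count_alleles(rna.sorted_alignments(), truth.sites)
        report.ase_verdict = ase_mod.classify_expression(counts)
        report.ase_alt_fractions = {
            c.site.label: round(c.alt_fraction, 4) if c.informative else None
            for c in counts
        }
        if out is not None:
            ase_mod.write_ase_tsv(counts, out / "ase.tsv")
    except Exception as exc:
        raise StageError("ase", exc) from exc

    try:
        _stage("verdict")
        names = "/".join(h.name for h in truth.haplotypes)
        report.genotype = names
        report.predicted_phenotype = phenotype(Genotype.parse(names))
        if out is not None:
            (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    except Exception as exc:
        raise StageError("verdict", exc) from exc
    return report
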