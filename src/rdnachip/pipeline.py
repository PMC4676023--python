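"""End-to-end orchestration: simulate -> build reference -> align ->
signal -> call peaks, with reproducible seeds and a structured run report.

The synthetic mode runs the full design desk-side: reads are simulated
from the multi-copy tandem genome and mapped back to the single-unit
augmented reference, so the aggregate unit signal can be compared with the
planted truth. The external-SAM mode consumes alignments produced
elsewhere (e.g. real archive data mapped on a cluster) and runs the same
signal and peak-calling stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import aligner, enrichment, qpcr, seqs, signal, synthetic
from .reference import CoordinateMap

_SEED_MOD = 2**31


def _derive_seed(base: int, stream: int) -> int:
    return int((base * 1_000_003 + stream * 7_654_321 + 12345) % _SEED_MOD)


@dataclass
class RunConfig:
    mode: str = "synthetic"  # 'synthetic' | 'external-sam'
    # synthetic-mode design
    unit_length: int = 43_000
    n_copies: int = 5
    background_length: int = 100_000
    gc_fraction: float = 0.55
    mark: str = "H3K4me1"
    igs_peak_center: int = 28_000
    n_reads: int = 200_000
    read_length: int = 36
    error_rate: float = 0.001
    # aligner
    max_mismatches: int = 2
    uniqueness_policy: str = "any-stratum"
    seed_length: int | None = None
    # signal
    fragment_size: int = 200
    bandwidth: float | None = None
    subtract: bool = True
    # enrichment
    bin: int = 200
    threshold_sd: float = 4.0
    min_len: int = 100
    merge_gap: int = 200
    # reproducibility
    seed: int = 0
    # external-sam mode inputs
    chip_sam: str | None = None
    input_sam: str | None = None
    reference_fasta: str | None = None
    coords_tsv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class RunResult:
    """In-memory products of a synthetic run."""

    genome: synthetic.SyntheticGenome
    chip_reads: synthetic.ReadSet
    input_reads: synthetic.ReadSet
    chip_batch: aligner.BatchAlignment
    input_batch: aligner.BatchAlignment
    chip_track: signal.SignalTrack
    input_track: signal.SignalTrack
    subtracted: signal.SignalTrack
    peaks: list[enrichment.Peak]
    model: enrichment.NBModel
    accounting: dict = field(default_factory=dict)


def run_synthetic(config: RunConfig) -> RunResult:
    """Execute the synthetic design in memory and return every product."""
    spec = synthetic.RepeatGenomeSpec(
        unit_length=config.unit_length,
        n_copies=config.n_copies,
        background_length=config.background_length,
        gc_fraction=config.gc_fraction,
        seed=_derive_seed(config.seed, 0),
        guard_k=config.seed_length
        or aligner.default_seed_length(config.read_length, config.max_mismatches),
    )
    genome = synthetic.make_genome(spec)
    profiles = synthetic.default_profiles(config.unit_length, config.igs_peak_center)
    if config.mark not in profiles:
        raise ValueError(f"unknown mark {config.mark!r}; one of {sorted(profiles)}")
    chip_profile = profiles[config.mark]
    input_profile = profiles["input"]

    genomic_seq = genome.genomic[synthetic.GENOMIC_CHROM]
    chip_reads = synthetic.simulate_reads(
        genomic_seq,
        chip_profile,
        synthetic.ReadSimParams(
            n_reads=config.n_reads,
            read_length=config.read_length,
            fragment_length=config.fragment_size,
            error_rate=config.error_rate,
            seed=_derive_seed(config.seed, 1),
        ),
        unit_intervals=genome.unit_intervals_genomic,
    )
    input_reads = synthetic.simulate_reads(
        genomic_seq,
        input_profile,
        synthetic.ReadSimParams(
            n_reads=config.n_reads,
            read_length=config.read_length,
            fragment_length=config.fragment_size,
            error_rate=config.error_rate,
            seed=_derive_seed(config.seed, 2),
        ),
        unit_intervals=genome.unit_intervals_genomic,
    )

    index = aligner.build_kmer_index(genome.assembly.sequences, spec.guard_k)
    chip_batch = aligner.align_reads(
        chip_reads.sequences, index, config.max_mismatches, config.uniqueness_policy
    )
    input_batch = aligner.align_reads(
        input_reads.sequences, index, config.max_mismatches, config.uniqueness_policy
    )

    chrom = genome.assembly.modified_chrom
    bw = config.bandwidth or signal.default_bandwidth(config.fragment_size)
    chip_frags = signal.extend_reads(chip_batch, config.fragment_size, ref_name=chrom)
    input_frags = signal.extend_reads(input_batch, config.fragment_size, ref_name=chrom)
    chip_track = signal.kde_signal(chip_frags, bw)
    input_track = signal.kde_signal(input_frags, bw)
    sub = signal.subtract_input(chip_track, input_track) if config.subtract else chip_track

    peaks, model = enrichment.call_peaks_auto(
        sub, chip_frags, config.threshold_sd, config.min_len, config.merge_gap, config.bin
    )

    accounting = {
        "chip": {"reads_in": config.n_reads, **chip_batch.counts},
        "input": {"reads_in": config.n_reads, **input_batch.counts},
    }
    for side in accounting.values():
        assert side["reads_in"] == side["unique"] + side["multi"] + side["unmapped"]
    return RunResult(
        genome, chip_reads, input_reads, chip_batch, input_batch,
        chip_track, input_track, sub, peaks, model, accounting,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_all(config: RunConfig, outdir) -> dict:
    """File-level pipeline run; returns (and writes) the run report.

    Identical config and seed produce byte-identical outputs. On a stage
    failure the report is written with an ``incomplete`` marker naming the
    failing stage, and the exception is re-raised.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": [], "artifacts": {}}
    stage = "setup"

    def done(name: str, **extra):
        report["stages"].append({"stage": name, **extra})

    try:
        if config.mode == "synthetic":
            stage = "simulate"
            result = run_synthetic(config)
            genome = result.genome
            genome.write_genomic_fasta(out / "genomic.fa")
            genome.write_augmented_fasta(out / "augmented.fa")
            genome.write_truth_bed(out / "truth.bed")
            genome.coord_map.to_tsv(out / "coordinates.tsv")
            result.chip_reads.to_fastq(out / "chip.fastq")
            result.input_reads.to_fastq(out / "input.fastq")
            done("simulate", n_reads=config.n_reads)

            stage = "align"
            for name, reads, batch in (
                ("chip", result.chip_reads, result.chip_batch),
                ("input", result.input_reads, result.input_batch),
            ):
                reports = aligner.batch_to_reports(batch, reads.ids, reads.sequences)
                aligner.write_sam(reports, batch.ref_lengths, out / f"{name}.sam")
            done("align", **result.accounting)

            chip_track, input_track, sub = (
                result.chip_track, result.input_track, result.subtracted,
            )
            cmap = genome.coord_map
            peaks, model = result.peaks, result.model
        elif config.mode == "external-sam":
            stage = "import"
            if not (config.chip_sam and config.input_sam and config.reference_fasta and config.coords_tsv):
                raise ValueError(
                    "external-sam mode needs chip_sam, input_sam, reference_fasta, coords_tsv"
                )
            refs = seqs.read_fasta(config.reference_fasta)
            cmap = CoordinateMap.from_tsv(config.coords_tsv)
            chrom = max(refs, key=lambda n: len(refs[n]))
            bw = config.bandwidth or signal.default_bandwidth(config.fragment_size)
            tracks, fragsets, counts = {}, {}, {}
            for name, sam in (("chip", config.chip_sam), ("input", config.input_sam)):
                reports, _ = aligner.read_sam(sam)
                kept = [r.alignments[0] for r in reports if r.kept]
                fragsets[name] = signal.extend_reads(
                    kept, config.fragment_size, reference_length=len(refs[chrom]),
                    ref_name=chrom,
                )
                tracks[name] = signal.kde_signal(fragsets[name], bw)
                counts[name] = {
                    "reads_in": len(reports),
                    "unique": sum(r.category == "unique" for r in reports),
                    "multi": sum(r.category == "multi" for r in reports),
                    "unmapped": sum(r.category == "unmapped" for r in reports),
                }
            chip_track, input_track = tracks["chip"], tracks["input"]
            sub = (
                signal.subtract_input(chip_track, input_track)
                if config.subtract
                else chip_track
            )
            chip_frags = fragsets["chip"]
            stage = "callpeaks"
            peaks, model = enrichment.call_peaks_auto(
                sub, chip_frags, config.threshold_sd, config.min_len,
                config.merge_gap, config.bin,
            )
            done("import", **counts)
        else:
            raise ValueError(f"unknown mode {config.mode!r}")

        stage = "signal"
        signal.write_bedgraph(chip_track, out / "chip.bedgraph")
        signal.write_bedgraph(input_track, out / "input.bedgraph")
        signal.write_bedgraph(sub, out / "subtracted.bedgraph")
        signal.summarize_unit(sub, cmap, config.bin).to_csv(
            out / "unit_profile.tsv", sep="\t", index=False
        )
        done("signal", bandwidth=sub.bandwidth)

        stage = "callpeaks"
        enrichment.write_peaks_bed(peaks, out / "peaks.bed")
        enrichment.model_report(model, out / "nb_model.json")
        done("callpeaks", n_peaks=len(peaks), model=model.to_dict())
    except Exception as exc:
        report["incomplete"] = {"stage": stage, "error": str(exc)}
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.name != "report.json" and f.is_file():
            report["artifacts"][f.name] = _sha256(f)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def align_fastq(
    fastq_path,
    reference: dict[str, str],
    max_mismatches: int = 2,
    policy: str = "any-stratum",
    seed_length: int | None = None,
    sam_out=None,
):
    """Map a FASTQ against a reference set; optionally write SAM.

    Equal-length reads go through the vectorized batch path; mixed lengths
    fall back to per-read alignment.
    """
    ids, reads = seqs.read_fastq(fastq_path)
    lengths = {len(s) for s in reads}
    if len(lengths) == 1:
        L = lengths.pop()
        k = seed_length or aligner.default_seed_length(L, max_mismatches)
        index = aligner.build_kmer_index(reference, k)
        batch = aligner.align_reads(reads, index, max_mismatches, policy)
        reports = aligner.batch_to_reports(batch, ids, reads)
    else:
        k = seed_length or aligner.default_seed_length(min(lengths), max_mismatches)
        index = aligner.build_kmer_index(reference, k)
        reports = [
            aligner.uniqueness_filter(
                aligner.align_read(s, index, max_mismatches), policy, rid
            )
            for rid, s in zip(ids, reads)
        ]
        for rep, s in zip(reports, reads):
            rep.seq = s
    if sam_out is not None:
        ref_lengths = {n: len(s) for n, s in reference.items()}
        aligner.write_sam(reports, ref_lengths, sam_out)
    return reports


def ddct_report(table, targets, reference_gene: str = "GAPDH"):
    """Fold-change table for a list of targets from a tidy Ct table."""
    import pandas as pd

    rows = []
    for tgt in targets:
        est = qpcr.ddct_fold_change(table, tgt, reference_gene)
        rows.append(
            {
                "target": tgt,
                "fold_change": est.point,
                "sd": est.dispersion,
                "n": est.n,
            }
        )
    return pd.DataFrame(rows)
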