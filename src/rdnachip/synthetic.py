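"""Synthetic study-design generator: toy tandem rDNA genomes, planted
enrichment profiles, sequencing reads and replicated qPCR tables.

The generator mirrors the geometry the analysis is built for: a multi-copy
tandem array of an identical ~43 kb repeat unit embedded in unique
background sequence, together with a matching single-unit augmented
reference. Enrichment profiles plant mark-specific structure on the unit —
punctate peaks near the promoter and at ~28 kb in the intergenic spacer for
enhancer/promoter marks, broad domains for elongation and repressive marks,
and a flat profile for input chromatin. Everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seqs
from .reference import AugmentedAssembly, CoordinateMap, RdnaUnit, build_augmented_assembly

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))

GENOMIC_CHROM = "chr_array"
BACKGROUND_CHROM = "chr_bg"


@dataclass(frozen=True)
class RepeatGenomeSpec:
    """Parameters of the toy genome: an identical-copy tandem array in
    unique background.

    ``guard_k`` is the aligner seed length; the background is rejection-
    sampled so that it shares no ``guard_k``-mer (either strand) with the
    unit, which makes uniqueness reasoning in tests exact.
    """

    unit_length: int = 43_000
    n_copies: int = 5
    background_length: int = 100_000
    gc_fraction: float = 0.55
    seed: int = 0
    guard_k: int = 12

    def __post_init__(self):
        if self.unit_length < 1000:
            raise ValueError("unit_length must be >= 1000")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if self.background_length < 0:
            raise ValueError("background_length must be >= 0")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.guard_k < 8:
            raise ValueError("guard_k must be >= 8")


@dataclass(frozen=True)
class PeakSpec:
    center: int  # 1-based unit bp
    fwhm: int
    fold: float

    def __post_init__(self):
        if self.fold < 1:
            raise ValueError("peak fold must be >= 1")


@dataclass(frozen=True)
class DomainSpec:
    start: int  # 1-based unit bp, inclusive
    end: int  # inclusive
    fold: float

    def __post_init__(self):
        if self.fold < 1:
            raise ValueError("domain fold must be >= 1")
        if self.start > self.end:
            raise ValueError("domain start must be <= end")


@dataclass(frozen=True)
class EnrichmentProfile:
    """Planted per-base fragment-midpoint intensity over the repeat unit.

    lambda(x) = baseline * max(1, sum of Gaussian peak folds and
    rectangular domain folds at x); the floor at 1 keeps the baseline
    sampling rate everywhere.
    """

    mark_name: str
    peaks: tuple[PeakSpec, ...] = ()
    domains: tuple[DomainSpec, ...] = ()
    baseline: float = 1.0

    def unit_intensity(self, unit_length: int) -> np.ndarray:
        x = np.arange(1, unit_length + 1, dtype=float)
        contrib = np.zeros(unit_length)
        for pk in self.peaks:
            if not 1 <= pk.center <= unit_length:
                raise ValueError("peak center outside the unit")
            sd = pk.fwhm / _FWHM_TO_SD
            contrib += pk.fold * np.exp(-0.5 * ((x - pk.center) / sd) ** 2)
        for dom in self.domains:
            contrib[max(dom.start - 1, 0) : dom.end] += dom.fold
        return self.baseline * np.maximum(1.0, contrib)


def default_profiles(unit_length: int = 43_000, igs_peak_center: int = 28_000) -> dict[str, EnrichmentProfile]:
    """Mark-specific default profiles emulating the repeat-unit chromatin map.

    H3K4me1 is punctate near the promoter and at the ~28 kb intergenic-
    spacer site; H3K27ac, H3K4me3 and CTCF sit just upstream of the TSS
    (the unit's 3' end, since the deposited unit begins at the TSS);
    H3K36me3 covers the whole unit as an elongation domain; H3K27me3 is a
    broad repressive domain over the intergenic spacer; input is flat.
    Positions scale proportionally for non-default unit lengths.
    """

    def u(pos_on_43k: float) -> int:
        return max(1, min(unit_length, int(round(pos_on_43k / 43_000 * unit_length))))

    igs = max(1, min(unit_length, igs_peak_center))
    coding_end = u(13_314)
    return {
        "H3K4me1": EnrichmentProfile(
            "H3K4me1",
            peaks=(PeakSpec(u(42_500), 800, 4.0), PeakSpec(igs, 600, 5.0)),
        ),
        "H3K27ac": EnrichmentProfile("H3K27ac", peaks=(PeakSpec(u(42_800), 600, 5.0),)),
        "H3K4me3": EnrichmentProfile("H3K4me3", peaks=(PeakSpec(u(42_800), 600, 6.0),)),
        "CTCF": EnrichmentProfile("CTCF", peaks=(PeakSpec(u(42_700), 400, 8.0),)),
        "H3K36me3": EnrichmentProfile(
            "H3K36me3", domains=(DomainSpec(1, unit_length, 2.0),)
        ),
        "H3K27me3": EnrichmentProfile(
            "H3K27me3", domains=(DomainSpec(coding_end + 1, unit_length, 2.5),)
        ),
        "input": EnrichmentProfile("input"),
    }


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return rng.choice(4, size=n, p=[at, gc / 2.0, gc / 2.0, at]).astype(np.uint8)


def _sample_background(
    rng: np.random.Generator,
    length: int,
    gc: float,
    unit_enc: np.ndarray,
    k: int,
    max_rounds: int = 100,
) -> np.ndarray:
    """Background free of any unit k-mer (either strand), by rejection.

    Colliding windows are locally resampled; an over-constrained spec
    (e.g. tiny alphabet budget) fails after ``max_rounds`` rounds.
    """
    bg = _random_bases(rng, length, gc)
    if length < k:
        return bg
    _, fwd = seqs.kmer_codes(unit_enc, k)
    _, rev = seqs.kmer_codes(seqs.revcomp_arr(unit_enc), k)
    forbidden = np.unique(np.concatenate([fwd, rev]))
    for _ in range(max_rounds):
        pos, codes = seqs.kmer_codes(bg, k)
        bad = pos[np.isin(codes, forbidden)]
        if bad.size == 0:
            return bg
        hit = np.unique((bad[:, None] + np.arange(k)).ravel())
        bg[hit] = _random_bases(rng, hit.size, gc)
    raise RuntimeError(
        "background rejection sampling failed; spec is over-constrained "
        f"(k={k}, background_length={length})"
    )


@dataclass
class SyntheticGenome:
    """A generated toy genome with its augmented reference and truth."""

    spec: RepeatGenomeSpec
    unit: RdnaUnit
    genomic: dict[str, str]
    assembly: AugmentedAssembly
    coord_map: CoordinateMap
    truth: list[tuple[str, int, int, str]]  # (chrom, start, end, name), 0-based half-open

    @property
    def unit_intervals_genomic(self) -> list[tuple[int, int]]:
        return [(s, e) for _, s, e, _ in self.truth]

    @property
    def unit_interval_augmented(self) -> tuple[int, int]:
        off = self.assembly.unit_offset
        return (off, off + self.unit.length)

    def write_genomic_fasta(self, path) -> None:
        seqs.write_fasta(self.genomic, path)

    def write_augmented_fasta(self, path) -> None:
        seqs.write_fasta(self.assembly.sequences, path)

    def write_truth_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e, name in self.truth:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def make_genome(spec: RepeatGenomeSpec) -> SyntheticGenome:
    """Build the multi-copy genomic reference, the single-unit augmented
    reference, and the truth annotation of unit placements."""
    rng = np.random.default_rng(spec.seed)
    unit_enc = _random_bases(rng, spec.unit_length, spec.gc_fraction)
    unit_seq = seqs.decode(unit_enc)
    bg = _sample_background(
        rng, spec.background_length, spec.gc_fraction, unit_enc, spec.guard_k
    )
    left_len = spec.background_length // 2
    left, right = seqs.decode(bg[:left_len]), seqs.decode(bg[left_len:])

    array = unit_seq * spec.n_copies
    genomic = {GENOMIC_CHROM: left + array + right}
    truth = [
        (
            GENOMIC_CHROM,
            left_len + i * spec.unit_length,
            left_len + (i + 1) * spec.unit_length,
            f"unit_{i + 1}",
        )
        for i in range(spec.n_copies)
    ]

    unit = RdnaUnit(
        sequence=unit_seq,
        tss_unit_pos=1,
        coding_end_unit_pos=min(13_314, spec.unit_length),
    )
    assembly, cmap = build_augmented_assembly(
        {BACKGROUND_CHROM: left + right}, unit, BACKGROUND_CHROM, placement="proximal_tip"
    )
    return SyntheticGenome(
        spec=spec,
        unit=unit,
        genomic=genomic,
        assembly=assembly,
        coord_map=cmap,
        truth=truth,
    )


@dataclass(frozen=True)
class ReadSimParams:
    n_reads: int = 200_000
    read_length: int = 36
    fragment_length: int = 200
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length > self.fragment_length:
            raise ValueError("read_length must be <= fragment_length")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must lie in [0, 0.1]")


@dataclass
class ReadSet:
    ids: list[str]
    sequences: list[str]
    params: ReadSimParams
    # truth of each read: fragment start on the source reference and strand
    fragment_starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    strands: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))

    @property
    def fragment_midpoints(self) -> np.ndarray:
        return self.fragment_starts + self.params.fragment_length / 2.0

    def to_fastq(self, path) -> None:
        seqs.write_fastq(path, self.ids, self.sequences)


def simulate_reads(
    sequence: str,
    profile: EnrichmentProfile,
    params: ReadSimParams,
    unit_intervals: list[tuple[int, int]] | None = None,
) -> ReadSet:
    """Draw single-end reads whose fragment midpoints follow the planted
    intensity.

    The per-base intensity is the profile's baseline everywhere, overlaid
    with the profile's unit intensity across each (start, end) interval in
    ``unit_intervals`` (each must span exactly one unit length). Fragments
    of fixed length are placed with probability proportional to the
    intensity at their midpoint; the read is the first ``read_length``
    bases of the fragment on a uniformly chosen strand, with i.i.d.
    substitution errors.
    """
    ref_len = len(sequence)
    if ref_len == 0:
        raise ValueError("empty reference")
    if params.fragment_length > ref_len:
        raise ValueError("fragment longer than the reference")
    rng = np.random.default_rng(params.seed)
    flen, rlen = params.fragment_length, params.read_length

    lam = np.full(ref_len, float(profile.baseline))
    for s, e in unit_intervals or []:
        lam[s:e] = profile.unit_intensity(e - s)

    n_starts = ref_len - flen + 1
    weights = lam[flen // 2 : flen // 2 + n_starts]
    cdf = np.cumsum(weights)
    if params.n_reads == 0:
        return ReadSet([], [], params)
    starts = np.searchsorted(cdf, rng.random(params.n_reads) * cdf[-1], side="right")
    strands = rng.integers(0, 2, params.n_reads).astype(np.int8)  # 0 = +, 1 = -

    enc_ref = seqs.encode_ref(sequence)
    offs = np.arange(rlen)
    fwd_idx = starts[:, None] + offs
    rev_idx = (starts + flen - rlen)[:, None] + offs
    mat = np.where(strands[:, None] == 0, enc_ref[fwd_idx], enc_ref[rev_idx])
    rev_rows = strands == 1
    mat[rev_rows] = seqs.revcomp_arr(mat[rev_rows])

    if params.error_rate > 0:
        err = rng.random(mat.shape) < params.error_rate
        shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
        mat = np.where(err, (mat + shift) % 4, mat).astype(np.uint8)

    flat = seqs.decode(mat.ravel())
    sequences = [flat[i * rlen : (i + 1) * rlen] for i in range(params.n_reads)]
    ids = [f"r{i:07d}" for i in range(params.n_reads)]
    return ReadSet(ids, sequences, params, starts.astype(np.int64), strands)


@dataclass(frozen=True)
class QpcrSimParams:
    """Replicated RT-qPCR simulation: per-target true fold changes between
    a control and a treatment condition, with Gaussian Ct noise.

    The treated-condition Ct of a target is shifted by -log2(true_fold)
    relative to control (perfect amplification efficiency of 2); the
    reference gene is unshifted.
    """

    true_fold: dict[str, float] = field(default_factory=lambda: {"pre-rRNA_5ETS": 0.8})
    ct_baseline: float = 22.0
    noise_sd: float = 0.1
    n_reps: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(f <= 0 for f in self.true_fold.values()):
            raise ValueError("true folds must be > 0")


def simulate_qpcr(params: QpcrSimParams, reference_gene: str = "GAPDH") -> pd.DataFrame:
    """Generate a tidy replicated Ct table for ddCt analysis.

    Columns: sample_id, condition, assay, target, ct, input_fraction.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    targets = dict(params.true_fold)
    targets[reference_gene] = 1.0
    for target, fold in targets.items():
        for condition in ("control", "treatment"):
            shift = 0.0 if condition == "control" else -np.log2(fold)
            for rep in range(1, params.n_reps + 1):
                ct = params.ct_baseline + shift + rng.normal(0.0, params.noise_sd)
                rows.append(
                    {
                        "sample_id": f"{condition}_rep{rep}",
                        "condition": condition,
                        "assay": "rt",
                        "target": target,
                        "ct": ct,
                        "input_fraction": np.nan,
                    }
                )
    return pd.DataFrame(rows)
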