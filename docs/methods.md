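# Methods

## The problem and the reference trick

The rDNA repeat is a multi-copy tandem array: every short read from it
maps equally well to every copy, so under a "discard multi-mappers" policy
an ordinary reference loses the locus entirely. The analysis therefore
builds an augmented assembly carrying exactly one unit: the target
chromosome is first stripped of its long placeholder N-run (an unsequenced
centromeric gap; `min_run` defaults to 1000 bp so incidental short N
stretches survive), then the unit is prepended at the proximal tip (or at
a caller-supplied offset — the exact placement on the real chromosome is
not knowable, so it is a parameter, not a guess). All signal over the unit
is then the aggregate over all genomic copies, active and silent alike;
nothing in this pipeline can discriminate copy states.

Three coordinate systems are maintained. Assembly coordinates are 0-based
half-open (as in BED/bedGraph output); unit coordinates are 1-based; and
promoter-relative coordinates are signed with no position 0 (+1 at the
TSS). Because the deposited unit begins at the TSS, upstream (negative)
promoter positions wrap to the unit's 3′ end — the unit is treated as a
circular permutation of the repeat — which is what makes the −57…+43
promoter amplicon a contiguous 100 nt in repeat context. Amplicon length
is `end − start` when the span crosses the TSS and `end − start + 1`
otherwise.

## Alignment and the uniqueness filter

Alignment is ungapped (Hamming) with a budget of two mismatches,
implemented as seed-and-extend over a k-mer index with
`k = floor(L / (mm + 1))` (floor 8): partitioning the read into `mm + 1`
disjoint seeds guarantees by pigeonhole that every alignment within the
budget has at least one exact seed, so the search is exhaustive — a
property the suite verifies against an every-position scan. Reference
ambiguity codes never match any read base. Output order is deterministic
(`ref, start, strand`).

The uniqueness filter keeps a read only if it has exactly one reportable
alignment. By default every alignment within the mismatch budget is
reportable ("any-stratum"): a read with one perfect and one two-mismatch
alignment is discarded, the conservative reading of `-m 1`-style
filtering. A "best-stratum" policy (count only minimal-mismatch
alignments) is available as a switch. Unmapped and multi-mapped reads are
accounted separately so that reads in = unique + multi + unmapped at every
stage.

The batch aligner is a vectorized re-implementation of the per-read path
and is property-tested to produce identical alignment sets and categories;
the per-read path is the specification, the batch path the workhorse.

## Signal model

Kept reads are extended 3′-ward to the fragment size (200 bp, matching
200–1000 bp sonication with single-end sequencing), clipped at reference
edges. The track value at base x is the Gaussian kernel density of
fragment midpoints with bandwidth σ (default `200 / (2√(2 ln 2))` ≈ 85 bp,
i.e. kernel FWHM equal to the fragment size — the convention of
density-based callers), scaled to reads-per-million by the kept-read
count. Midpoints lie on a half-integer lattice, so the density is computed
exactly as a convolution on a half-base grid (FFT-based; values floored at
0 against round-off). The kernel is truncated at 8σ: the discarded tail
mass (<1e-14) is far below every tolerance used anywhere in the package,
while keeping the support bounded. Input subtraction happens per base on
the reads-per-million scale — without the common scale, unequal library
depths would make subtraction meaningless — and negative results are
clamped to zero with the clamped positions flagged, since downstream count
models need non-negative signal. Subtraction precedes peak calling;
`--no-subtract`-style behavior is available through the `subtract` config
switch.

## Enrichment testing

Fragment midpoints are binned (200 bp default; a midpoint exactly on a
boundary belongs to the right bin). The background is a negative binomial
fitted by the method of moments — μ the sample mean, r = m²/(v − m) — on
bins outside first-pass track candidates; when v ≤ m the model degrades to
Poisson (the fit is then not over-dispersed, and the NB has no valid r).
Moments were chosen over maximum likelihood because they are closed-form,
and their recovery is directly testable by simulation. At least 2 bins are
required for a fit; the automatic caller refuses to exclude candidate bins
if fewer than 10 background bins would remain.

Candidate peaks are maximal runs where the track strictly exceeds
mean + 4·sd of the track background; the background statistics are
re-estimated once with first-pass candidates masked. Strict inequality
makes a constant track call nothing (a global threshold on a degenerate
sd would otherwise flag everything). Runs closer than 200 bp merge, runs
shorter than 100 bp drop. Each peak's midpoint count, rescaled to per-bin
units, gets an upper-tail NB p-value (P(X ≥ k); p(0) = 1 exactly), and BH
correction across the called peaks yields q-values — the correction is a
deliberate addition, reported as such, since count-based peak p-values are
always computed in batches. Summits break ties leftmost for determinism.

Note a structural feature of the augmented design: the deposited unit
carries n-copies-fold the depth of the single-copy flanks, so a background
fitted across the whole chromosome is bimodal and strongly over-dispersed.
This is faithful to the design (the real analysis has the same property —
rDNA coverage vastly exceeds the genome average) and makes the NB
threshold conservative. Calibration of the p-values as a null is therefore
assessed where the null actually holds: on flat-input simulations over the
interior of the unit (edge bins within 500 bp excluded, since fragment
clipping and copy-junction read loss distort midpoint density there).

## The synthetic study design

The generator reproduces the geometry the analysis assumes, not the
biology of real libraries. Defaults are the study conditions: a 43,000 bp
unit, 5 identical copies (a desk-scale stand-in for hundreds), 100 kb of
unique background at GC 0.55, 2×10⁵ single-end 36 bp reads per library,
200 bp fragments, substitution error 0.001. Read length and depth are not
stated for the original archive runs; 36 bp and 2×10⁵ are chosen as
ENCODE-era realistic and desk-fast. The background is rejection-sampled so
it shares no aligner-seed-length k-mer (either strand) with the unit,
which makes uniqueness reasoning in tests exact rather than statistical;
colliding windows are locally resampled with a bounded retry count.

Mark profiles plant per-base fragment-midpoint intensity
λ(x) = baseline · max(1, Σ peak/domain folds at x), with Gaussian-shaped
peaks (given center, FWHM, fold) and rectangular domains: H3K4me1 peaks
near the promoter (unit 42,500) and at the ~28 kb IGS site; H3K27ac,
H3K4me3 and CTCF just upstream of the TSS (the unit's 3′ end); H3K36me3 a
whole-unit elongation domain; H3K27me3 a broad IGS domain; input flat.
Fragments are placed by midpoint intensity (symmetric around planted
centers, unlike start-placement), the read is the fragment's first
`read_length` bases on a uniform strand, and errors are i.i.d.
substitutions. No indels, duplicates, paired ends or quality modeling —
so passing tests demonstrate the pipeline's statistical behavior under its
own assumptions, not robustness to real-library artifacts (mappability
bias, PCR duplication, copy-to-copy sequence variation between rDNA
units).

The qPCR generator encodes a per-target fold between conditions as a Ct
shift of −log₂(fold) (perfect efficiency 2.0), Gaussian cycle noise, an
unshifted reference gene, and ≥2 replicates; ΔΔCt analysis inverts it
exactly at zero noise, which is the basis of the recovery tests.

## qPCR conventions

Percent input adjusts the input Ct by log₂(1/input_fraction) before
`100·2^(ΔCt)`; the input fraction defaults to 0.1 and is configurable
(the original protocol does not state it — results scale linearly, and
the estimator is invariant to any common Ct offset). Replicates are
independent experiments; technical wells are averaged before tables enter
the estimators, and dispersions are across experiments. The t-test
defaults to Welch (robust to unequal variances; the classical
equal-variance Student variant is a flag, and comparisons are unpaired).
Degenerate zero-variance inputs return p = 1 for equal means and a flagged
p = 0 otherwise. Methylation-resistance fractions above 1 are clipped with
a flag (physically impossible, signals assay noise); no-amplification
digests are censored at the detection floor implied by the cycle ceiling
(40 by default) and reported as "< floor", which is how a
methylation-insensitive MspI control should always behave.

## Determinism and problem sizes

Every stochastic stage takes an explicit seed; pipeline stage seeds are
derived from the single run seed by a fixed affine map modulo 2³¹.
Identical configuration and seed give byte-identical FASTA/FASTQ/SAM/
bedGraph/BED outputs. The test suite runs the full study-scale design
(43 kb unit, 5 copies, 2×10⁵ + 2×10⁵ reads, 20 seeds for summit recovery)
in a few minutes on one CPU; unit tests use a 2 kb-unit toy genome with
the same geometry.

## Known limitations

Gapped alignment, base-quality-aware scoring and BAM/CRAM I/O are out of
scope (SAM text only; convert externally). The background model is global,
not locally estimated, so gradual coverage trends inflate the NB
dispersion rather than being tracked. Copy-state heterogeneity
(active/silent rDNA, CpG methylation differences between copies) is
invisible by construction. The GenBank unit reader takes the unit length
from the record and fixes the TSS at position 1, with the coding-region
end configurable (default 13,314 bp, ~13.3 kb); it does not parse feature
annotations.
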