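"""Single-unit augmented reference assembly and rDNA coordinate systems.

The human rDNA repeat is absent from standard genome assemblies, so signal
over the repeat is profiled against a custom assembly in which one full unit
is deposited on a chromosome whose long unsequenced gap (the centromeric
N-run) has been excised. Three coordinate systems coexist:

* assembly coordinates — 0-based positions on the modified chromosome;
* unit coordinates — 1-based positions within the deposited repeat unit;
* promoter-relative coordinates — signed positions around the transcription
  start site (+1 at the TSS, no position 0); negative positions wrap to the
  3' end of the unit because the deposited unit begins at the TSS and the
  promoter lies at the distal end of the intergenic spacer.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

_IUPAC = set("ACGTRYSWKMBDHVNacgtryswkmbdhvn")

DEFAULT_CODING_END = 13314  # ~13.3 kb coding region on the ~43 kb unit


@dataclass(frozen=True)
class RdnaUnit:
    """One full rDNA repeat unit, deposited starting at the TSS."""

    sequence: str
    tss_unit_pos: int = 1
    coding_end_unit_pos: int = DEFAULT_CODING_END

    def __post_init__(self):
        bad = set(self.sequence) - _IUPAC
        if bad:
            raise ValueError(f"non-IUPAC characters in unit sequence: {sorted(bad)[:5]}")
        if not 1 <= self.tss_unit_pos <= self.coding_end_unit_pos <= len(self.sequence):
            raise ValueError("require 1 <= tss <= coding_end <= unit length")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def length_kb(self) -> int:
        """Unit length rounded to the nearest kilobase."""
        return round(self.length / 1000)


def load_rdna_unit(path, fmt: str | None = None, coding_end: int | None = None) -> RdnaUnit:
    """Read the repeat unit from a GenBank or FASTA record.

    Intended for the real rDNA reference record (GenBank accession U13369,
    which begins at the TSS); the unit length is taken from the record
    length and the TSS is fixed at unit position 1.
    """
    path = str(path)
    if fmt is None:
        fmt = "genbank" if path.endswith((".gb", ".gbk", ".genbank")) else "fasta"
    rec = SeqIO.read(path, fmt)
    seq = str(rec.seq)
    if coding_end is None:
        coding_end = min(DEFAULT_CODING_END, len(seq))
    return RdnaUnit(sequence=seq, tss_unit_pos=1, coding_end_unit_pos=coding_end)


@dataclass(frozen=True)
class CoordinateMap:
    """Bidirectional map between assembly, unit and promoter coordinates."""

    unit_length: int
    unit_offset: int
    tss_unit_pos: int = 1

    def unit_to_assembly(self, unit_pos: int) -> int:
        """1-based unit position -> 0-based assembly position."""
        if not 1 <= unit_pos <= self.unit_length:
            raise ValueError(f"unit position {unit_pos} outside [1, {self.unit_length}]")
        return self.unit_offset + unit_pos - 1

    def assembly_to_unit(self, assembly_pos: int) -> int | None:
        """0-based assembly position -> 1-based unit position, or None outside the unit."""
        u = assembly_pos - self.unit_offset + 1
        if 1 <= u <= self.unit_length:
            return u
        return None

    def promoter_to_unit(self, promoter_pos: int) -> int:
        """Signed promoter-relative position (no zero) -> 1-based unit position.

        +k is k-th base from the TSS; -k wraps to the unit 3' end.
        """
        if promoter_pos == 0:
            raise ValueError("promoter coordinates have no position 0")
        if abs(promoter_pos) > self.unit_length:
            raise ValueError("promoter position beyond unit length")
        if promoter_pos > 0:
            u = self.tss_unit_pos + promoter_pos - 1
        else:
            u = self.unit_length + promoter_pos + self.tss_unit_pos
        if not 1 <= u <= self.unit_length:
            raise ValueError(f"promoter position {promoter_pos} maps outside the unit")
        return u

    def promoter_to_assembly(self, promoter_pos: int) -> int:
        return self.unit_to_assembly(self.promoter_to_unit(promoter_pos))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"unit_length\t{self.unit_length}\n")
            fh.write(f"unit_offset\t{self.unit_offset}\n")
            fh.write(f"tss_unit_pos\t{self.tss_unit_pos}\n")

    @classmethod
    def from_tsv(cls, path) -> "CoordinateMap":
        kv = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                k, v = line.rstrip("\n").split("\t")
                kv[k] = int(v)
        return cls(**kv)


@dataclass
class AugmentedAssembly:
    """Genome assembly carrying exactly one copy of the rDNA unit."""

    sequences: dict[str, str]
    modified_chrom: str
    unit_offset: int
    unit_length: int

    def __post_init__(self):
        chrom = self.sequences[self.modified_chrom]
        if self.unit_offset + self.unit_length > len(chrom):
            raise ValueError("unit extends past the modified chromosome")


def amplicon_length(start_promoter: int, end_promoter: int) -> int:
    """Length in nt of an amplicon given promoter-relative endpoints.

    Promoter coordinates skip 0, so a span crossing the TSS (start < 0 < end)
    contains end - start positions; a same-sign span contains
    end - start + 1.
    """
    if start_promoter == 0 or end_promoter == 0:
        raise ValueError("promoter coordinates have no position 0")
    if start_promoter > end_promoter:
        raise ValueError("require start <= end in promoter ordering")
    if start_promoter < 0 < end_promoter:
        return end_promoter - start_promoter
    return end_promoter - start_promoter + 1


def excise_n_runs(sequence: str, min_run: int = 1000) -> str:
    """Delete every maximal run of N (either case) of length >= min_run.

    Models the removal of a long unsequenced assembly gap (e.g. a
    centromeric placeholder) before depositing the repeat unit.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    return re.sub(f"[Nn]{{{min_run},}}", "", sequence)


def build_augmented_assembly(
    genome: dict[str, str],
    unit: RdnaUnit,
    target_chrom: str,
    placement: int | str = "proximal_tip",
    min_run: int = 1000,
) -> tuple[AugmentedAssembly, CoordinateMap]:
    """Deposit one rDNA unit on the N-excised target chromosome.

    ``placement`` is either the string ``"proximal_tip"`` (prepend the unit)
    or an integer offset into the excised chromosome at which to insert it.
    All other chromosomes pass through unchanged. A duplicate-unit hazard
    (the unit already present somewhere in the genome) raises a warning, not
    an error, because downstream uniqueness filtering would silently discard
    all unit reads.
    """
    if target_chrom not in genome:
        raise KeyError(f"target chromosome {target_chrom!r} not in genome")
    for name, seq in genome.items():
        if unit.sequence in seq:
            warnings.warn(
                f"rDNA unit sequence already present in {name}; "
                "unit reads will multi-map and be discarded",
                stacklevel=2,
            )
    excised = excise_n_runs(genome[target_chrom], min_run=min_run)
    if placement == "proximal_tip":
        offset = 0
    else:
        offset = int(placement)
        if not 0 <= offset <= len(excised):
            raise ValueError("placement offset outside the excised chromosome")
    modified = excised[:offset] + unit.sequence + excised[offset:]
    name = f"{target_chrom}_rDNA"
    sequences = {k: v for k, v in genome.items() if k != target_chrom}
    sequences[name] = modified
    assembly = AugmentedAssembly(
        sequences=sequences,
        modified_chrom=name,
        unit_offset=offset,
        unit_length=unit.length,
    )
    cmap = CoordinateMap(
        unit_length=unit.length, unit_offset=offset, tss_unit_pos=unit.tss_unit_pos
    )
    return assembly, cmap


# Nominal positions (kb along the unit) of the ChIP-qPCR primer panel;
# primer names follow the convention H<kb>.
PRIMER_UNIT_KB = {
    "H4": 4.0,
    "H8": 8.0,
    "H13": 13.0,
    "H18": 18.0,
    "H28": 28.0,
    "H42": 42.0,
    "H42.9": 42.9,
}
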