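"""Seed-and-extend alignment, uniqueness filtering and SAM interchange,
cross-checked against a brute-force Hamming scan."""

import numpy as np
import pytest

from rdnachip import aligner, seqs, synthetic
from oracles import brute_force_align, revcomp


def aln_tuple(a: aligner.Alignment):
    return (a.ref_name, a.start, a.strand, a.mismatches)


class TestKmerIndex:
    def test_repeated_kmer_positions(self):
        idx = aligner.build_kmer_index("ACGTACGT", 4)
        assert idx.positions("ACGT").tolist() == [0, 4]

    def test_absent_kmer_empty(self):
        idx = aligner.build_kmer_index("ACGTACGT", 4)
        assert idx.positions("TTTT").size == 0

    def test_entry_counting_identity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 500))
        idx = aligner.build_kmer_index(seq, 8)
        assert idx.n_entries == 500 - 8 + 1

    def test_ambiguous_windows_not_indexed(self):
        idx = aligner.build_kmer_index("ACGTNACGTACGT", 4)
        # the four windows covering the N are excluded
        assert idx.n_entries == 13 - 4 + 1 - 4
        assert idx.positions("ACGT").tolist() == [0, 5, 9]

    def test_k_longer_than_reference_rejected(self):
        with pytest.raises(ValueError):
            aligner.build_kmer_index("ACGT", 5)


class TestAlignRead:
    def test_exact_unique_substring(self, toy_genome):
        chrom = toy_genome.assembly.sequences[toy_genome.assembly.modified_chrom]
        read = chrom[500:530]  # inside the single deposited unit
        idx = aligner.build_kmer_index(toy_genome.assembly.sequences, 10)
        alns = aligner.align_read(read, idx)
        assert len(alns) == 1 and alns[0].mismatches == 0
        assert alns[0].start == 500 and alns[0].strand == "+"

    def test_three_mismatches_excluded(self, toy_genome):
        chrom = toy_genome.assembly.sequences[toy_genome.assembly.modified_chrom]
        read = list(chrom[100:130])
        for i in (12, 18, 24):  # outside the first pigeonhole seed
            read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        idx = aligner.build_kmer_index(toy_genome.assembly.sequences, 10)
        assert aligner.align_read("".join(read), idx, max_mismatches=2) == []

    def test_tandem_copy_read_hits_every_copy(self, toy_genome):
        chrom = toy_genome.genomic[synthetic.GENOMIC_CHROM]
        s = toy_genome.truth[0][1] + 700
        read = chrom[s : s + 30]
        idx = aligner.build_kmer_index(toy_genome.genomic, 10)
        alns = aligner.align_read(read, idx)
        oracle = brute_force_align(read, toy_genome.genomic, 2)
        assert len(alns) >= 3
        assert {aln_tuple(a) for a in alns} == oracle

    def test_strand_symmetry(self, toy_genome):
        chrom = toy_genome.genomic[synthetic.GENOMIC_CHROM]
        read = chrom[40:70]
        idx = aligner.build_kmer_index(toy_genome.genomic, 10)
        fwd = {(a.ref_name, a.start) for a in aligner.align_read(read, idx)}
        rev = aligner.align_read(revcomp(read), idx)
        assert {(a.ref_name, a.start) for a in rev} == fwd
        assert all(a.strand == "-" for a in rev if (a.ref_name, a.start) in fwd)

    def test_output_sorted_deterministically(self, toy_genome):
        chrom = toy_genome.genomic[synthetic.GENOMIC_CHROM]
        s = toy_genome.truth[0][1] + 40
        alns = aligner.align_read(
            chrom[s : s + 30], aligner.build_kmer_index(toy_genome.genomic, 10)
        )
        assert [aln_tuple(a) for a in alns] == sorted(aln_tuple(a) for a in alns)


class TestUniquenessFilter:
    A = aligner.Alignment("ref", 10, "+", 0, 30)
    B = aligner.Alignment("ref", 99, "-", 2, 30)

    def test_single_alignment_kept(self):
        rep = aligner.uniqueness_filter([self.A])
        assert rep.kept and rep.category == "unique"

    def test_two_alignments_discarded(self):
        rep = aligner.uniqueness_filter([self.A, self.B])
        assert not rep.kept and rep.category == "multi"

    def test_unmapped_distinct_from_multi(self):
        rep = aligner.uniqueness_filter([])
        assert not rep.kept and rep.category == "unmapped"

    def test_best_stratum_policy_rescues_clear_best(self):
        assert not aligner.uniqueness_filter([self.A, self.B]).kept
        rep = aligner.uniqueness_filter([self.A, self.B], policy="best-stratum")
        assert rep.kept

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            aligner.uniqueness_filter([self.A], policy="bowtie")


def _mutate(read, rng, n):
    out = list(read)
    for i in rng.choice(len(read), size=n, replace=False):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


class TestBruteForceEquivalence:
    def test_alignment_sets_match_oracle(self, rng):
        refs = {
            "chrA": "".join(rng.choice(list("ACGT"), 3000)),
            "chrB": "".join(rng.choice(list("ACGT"), 1500)),
        }
        idx = aligner.build_kmer_index(refs, 10)
        reads = []
        for _ in range(150):
            chrom = "chrA" if rng.random() < 0.7 else "chrB"
            s = int(rng.integers(0, len(refs[chrom]) - 30))
            read = refs[chrom][s : s + 30]
            if rng.random() < 0.5:
                read = revcomp(read)
            read = _mutate(read, rng, int(rng.integers(0, 4)))
            reads.append(read)
        reads.append("".join(rng.choice(list("ACGT"), 30)))  # likely unmappable
        for read in reads:
            got = {aln_tuple(a) for a in aligner.align_read(read, idx, 2)}
            assert got == brute_force_align(read, refs, 2)

    def test_batch_matches_per_read_path(self, rng):
        refs = {"chrA": "".join(rng.choice(list("ACGT"), 2000))}
        # include an exact repeat to force multi-mapping reads
        refs["chrA"] = refs["chrA"][:500] + refs["chrA"][100:160] + refs["chrA"][500:]
        idx = aligner.build_kmer_index(refs, 10)
        reads = []
        for _ in range(200):
            s = int(rng.integers(0, len(refs["chrA"]) - 30))
            read = refs["chrA"][s : s + 30]
            if rng.random() < 0.5:
                read = revcomp(read)
            reads.append(_mutate(read, rng, int(rng.integers(0, 3))))
        batch = aligner.align_reads(reads, idx, 2)
        reports = aligner.batch_to_reports(batch, [f"r{i}" for i in range(len(reads))])
        for read, rep in zip(reads, reports):
            alns = aligner.align_read(read, idx, 2)
            single = aligner.uniqueness_filter(alns, read_id=rep.read_id)
            assert [aln_tuple(a) for a in rep.alignments] == [aln_tuple(a) for a in alns]
            assert rep.category == single.category

    def test_batch_best_stratum_consistency(self, rng):
        refs = {"chrA": "".join(rng.choice(list("ACGT"), 1000))}
        refs["chrA"] += refs["chrA"][200:260]  # duplicated block
        idx = aligner.build_kmer_index(refs, 10)
        reads = [
            _mutate(refs["chrA"][int(rng.integers(0, 900)) :][:30], rng, int(rng.integers(0, 3)))
            for _ in range(100)
        ]
        batch = aligner.align_reads(reads, idx, 2, policy="best-stratum")
        for i, read in enumerate(reads):
            rep = aligner.uniqueness_filter(
                aligner.align_read(read, idx, 2), policy="best-stratum"
            )
            got = {0: "unique", 1: "multi", 2: "unmapped"}[int(batch.category[i])]
            assert got == rep.category


class TestSam:
    def make_reports(self, rng, n=100):
        cats = ["unique", "multi", "unmapped"]
        reports = []
        for i in range(n):
            cat = cats[int(rng.integers(0, 3))]
            seq = "".join(rng.choice(list("ACGT"), 30))
            if cat == "unmapped":
                alns = []
            else:
                k = 1 if cat == "unique" else int(rng.integers(2, 4))
                alns = sorted(
                    {
                        aligner.Alignment(
                            rng.choice(["chrA", "chrB"]).item(),
                            int(rng.integers(0, 400)),
                            "+-"[int(rng.integers(0, 2))],
                            int(rng.integers(0, 3)),
                            30,
                            f"read{i}",
                        )
                        for _ in range(k)
                    },
                    key=aligner.Alignment.sort_key,
                )
                if len(alns) == 1 and cat == "multi":
                    cat = "unique"
            reports.append(
                aligner.AlignmentReport(f"read{i}", alns, cat == "unique", cat, seq)
            )
        return reports

    def test_roundtrip_preserves_fields(self, rng, tmp_path):
        reports = self.make_reports(rng)
        path = tmp_path / "out.sam"
        aligner.write_sam(reports, {"chrA": 430, "chrB": 430}, path)
        back, ref_lengths = aligner.read_sam(path)
        assert ref_lengths == {"chrA": 430, "chrB": 430}
        assert len(back) == len(reports)
        for a, b in zip(reports, back):
            assert a.read_id == b.read_id
            assert a.category == b.category and a.kept == b.kept
            assert [aln_tuple(x) for x in a.alignments] == [
                aln_tuple(x) for x in b.alignments
            ]

    def test_sam_pos_is_one_based(self, tmp_path):
        rep = aligner.AlignmentReport(
            "r0", [aligner.Alignment("chrA", 99, "+", 0, 30, "r0")], True, "unique", "A" * 30
        )
        path = tmp_path / "one.sam"
        aligner.write_sam([rep], {"chrA": 1000}, path)
        line = [l for l in path.read_text().splitlines() if not l.startswith("@")][0]
        fields = line.split("\t")
        assert fields[3] == "100" and fields[1] == "0"

    def test_unmapped_record_convention(self, tmp_path):
        rep = aligner.AlignmentReport("r1", [], False, "unmapped", "A" * 30)
        path = tmp_path / "un.sam"
        aligner.write_sam([rep], {"chrA": 1000}, path)
        line = [l for l in path.read_text().splitlines() if not l.startswith("@")][0]
        fields = line.split("\t")
        assert fields[1] == "4" and fields[2] == "*" and fields[3] == "0"

    def test_malformed_sam_reported(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text("@HD\tVN:1.6\n@SQ\tSN:chrA\tLN:100\nnot-a-sam-line\n")
        with pytest.raises(ValueError, match="malformed SAM"):
            aligner.read_sam(path)
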