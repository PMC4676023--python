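"""Exhaustive ungapped short-read alignment with a uniqueness filter.

Reads are mapped by seed-and-extend over a k-mer index: a read allowed up
to ``max_mismatches`` Hamming mismatches is partitioned into
``max_mismatches + 1`` non-overlapping seeds, so by pigeonhole every
qualifying alignment carries at least one exact seed. All alignments on
both strands within the mismatch budget are reported.

The uniqueness filter reproduces the "-m 1"-style policy used when mapping
to a single-unit rDNA assembly: a read is kept only if it has exactly one
reportable alignment, so signal over the deposited unit aggregates all
repeat copies without multi-mapping artifacts. By default every alignment
within the mismatch budget is reportable ("any-stratum"); a "best-stratum"
policy that counts only minimal-mismatch alignments is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from . import seqs

STRAND_FWD = 0
STRAND_REV = 1
_STRAND_CHAR = {STRAND_FWD: "+", STRAND_REV: "-"}


@dataclass(frozen=True)
class Alignment:
    ref_name: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    mismatches: int
    length: int
    read_id: str | None = None

    @property
    def end(self) -> int:
        return self.start + self.length

    def sort_key(self):
        return (self.ref_name, self.start, self.strand)


@dataclass
class AlignmentReport:
    """Per-read alignment outcome and uniqueness verdict."""

    read_id: str
    alignments: list[Alignment]
    kept: bool
    category: str  # 'unique' | 'multi' | 'unmapped'
    seq: str | None = None


class KmerIndex:
    """Forward-strand k-mer positions for every reference sequence.

    Windows containing ambiguity codes are not indexed (they can never
    produce an exact seed match).
    """

    def __init__(self, references: dict[str, str] | str, k: int):
        if isinstance(references, str):
            references = {"ref": references}
        if not references:
            raise ValueError("empty reference set")
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > min(len(s) for s in references.values()):
            raise ValueError("k longer than the shortest reference")
        self.k = k
        self.ref_names = list(references)
        self.ref_seqs = dict(references)
        self.ref_lengths = {n: len(s) for n, s in references.items()}
        self._enc: dict[str, np.ndarray] = {}
        self._codes: dict[str, np.ndarray] = {}
        self._pos: dict[str, np.ndarray] = {}
        for name, seq in references.items():
            enc = seqs.encode_ref(seq)
            pos, codes = seqs.kmer_codes(enc, k)
            order = np.argsort(codes, kind="stable")
            self._enc[name] = enc
            self._codes[name] = codes[order]
            self._pos[name] = pos[order]

    @property
    def n_entries(self) -> int:
        """Indexed k-mer windows, counted with multiplicity."""
        return sum(p.size for p in self._pos.values())

    def positions(self, kmer: str, ref_name: str | None = None) -> np.ndarray:
        """All forward-strand occurrences of ``kmer`` (sorted)."""
        if len(kmer) != self.k:
            raise ValueError("query length must equal k")
        enc = seqs.encode_ref(kmer)
        if (enc >= 4).any():
            return np.empty(0, dtype=np.int64)
        code = 0
        for b in enc:
            code = code * 4 + int(b)
        names = [ref_name] if ref_name else self.ref_names
        out = []
        for name in names:
            lo = np.searchsorted(self._codes[name], code, "left")
            hi = np.searchsorted(self._codes[name], code, "right")
            out.append(self._pos[name][lo:hi])
        return np.sort(np.concatenate(out)) if out else np.empty(0, dtype=np.int64)


def build_kmer_index(references: dict[str, str] | str, k: int) -> KmerIndex:
    return KmerIndex(references, k)


def default_seed_length(read_length: int, max_mismatches: int = 2) -> int:
    """Pigeonhole seed length: floor(L / (mm + 1)), at least 8."""
    return max(8, read_length // (max_mismatches + 1))


def _seed_offsets(read_length: int, k: int, max_mismatches: int) -> list[int]:
    n_seeds = max_mismatches + 1
    if n_seeds * k > read_length:
        raise ValueError(
            f"read of length {read_length} cannot host {n_seeds} disjoint seeds of {k} bp"
        )
    return [i * k for i in range(n_seeds)]


def align_read(read: str, index: KmerIndex, max_mismatches: int = 2) -> list[Alignment]:
    """All ungapped alignments of a read within the mismatch budget.

    Deterministic output order: (ref_name, start, strand), '+' before '-'.
    """
    L = len(read)
    offsets = _seed_offsets(L, index.k, max_mismatches)
    enc_fwd = seqs.encode_reads([read])[0]
    out = []
    for strand, enc in ((STRAND_FWD, enc_fwd), (STRAND_REV, seqs.revcomp_arr(enc_fwd))):
        for name in index.ref_names:
            ref = index._enc[name]
            if L > ref.size:
                continue
            starts: set[int] = set()
            for off in offsets:
                win = enc[off : off + index.k]
                if (win >= 4).any():
                    continue
                code = 0
                for b in win:
                    code = code * 4 + int(b)
                lo = np.searchsorted(index._codes[name], code, "left")
                hi = np.searchsorted(index._codes[name], code, "right")
                for p in index._pos[name][lo:hi]:
                    s = int(p) - off
                    if 0 <= s <= ref.size - L:
                        starts.add(s)
            for s in sorted(starts):
                mism = int(np.count_nonzero(ref[s : s + L] != enc))
                if mism <= max_mismatches:
                    out.append(
                        Alignment(name, s, _STRAND_CHAR[strand], mism, L)
                    )
    out.sort(key=Alignment.sort_key)
    return out


def uniqueness_filter(
    alignments: list[Alignment], policy: str = "any-stratum", read_id: str = ""
) -> AlignmentReport:
    """Apply the single-reportable-alignment rule to one read's alignments.

    ``any-stratum`` (the "-m 1" analogue): keep iff exactly one alignment
    exists within the mismatch budget. ``best-stratum``: keep iff exactly
    one alignment attains the minimal mismatch count.
    """
    if policy in ("m1", "any-stratum"):
        reportable = alignments
    elif policy == "best-stratum":
        if alignments:
            best = min(a.mismatches for a in alignments)
            reportable = [a for a in alignments if a.mismatches == best]
        else:
            reportable = []
    else:
        raise ValueError(f"unknown uniqueness policy {policy!r}")
    if not alignments:
        return AlignmentReport(read_id, [], False, "unmapped")
    if len(reportable) == 1:
        return AlignmentReport(read_id, list(alignments), True, "unique")
    return AlignmentReport(read_id, list(alignments), False, "multi")


@dataclass
class BatchAlignment:
    """Vectorized alignment result for a set of equal-length reads.

    Stores every alignment found (flat arrays) plus the per-read category
    after the uniqueness filter. Kept alignments are the rows whose read is
    categorized 'unique'.
    """

    ref_names: list[str]
    ref_lengths: dict[str, int]
    read_length: int
    n_reads: int
    read_idx: np.ndarray  # per alignment
    chrom_idx: np.ndarray
    starts: np.ndarray
    strands: np.ndarray  # 0 fwd, 1 rev
    mismatches: np.ndarray
    category: np.ndarray  # per read: 0 unique, 1 multi, 2 unmapped
    policy: str = "any-stratum"
    kept_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    CAT_UNIQUE, CAT_MULTI, CAT_UNMAPPED = 0, 1, 2

    @property
    def counts(self) -> dict[str, int]:
        return {
            "unique": int(np.sum(self.category == self.CAT_UNIQUE)),
            "multi": int(np.sum(self.category == self.CAT_MULTI)),
            "unmapped": int(np.sum(self.category == self.CAT_UNMAPPED)),
        }

    def kept(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(read_idx, chrom_idx, starts, strands) of uniquely mapped reads."""
        r = self.kept_rows
        return self.read_idx[r], self.chrom_idx[r], self.starts[r], self.strands[r]


def _codes_at(mat: np.ndarray, off: int, k: int) -> np.ndarray:
    win = mat[:, off : off + k].astype(np.int64)
    valid = (win < 4).all(axis=1)
    codes = np.zeros(mat.shape[0], dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + np.where(win[:, j] < 4, win[:, j], 0)
    return np.where(valid, codes, -1)


def align_reads(
    reads: list[str] | np.ndarray,
    index: KmerIndex,
    max_mismatches: int = 2,
    policy: str = "any-stratum",
    chunk: int = 1_000_000,
) -> BatchAlignment:
    """Batch equivalent of ``align_read`` + ``uniqueness_filter``.

    Produces exactly the alignment set ``align_read`` would report for each
    read (a property-tested equivalence), with vectorized candidate
    generation and verification.
    """
    mat = reads if isinstance(reads, np.ndarray) else seqs.encode_reads(reads)
    n, L = (mat.shape[0], mat.shape[1]) if mat.size else (len(mat), 0)
    if n == 0:
        empty = np.empty(0, dtype=np.int64)
        return BatchAlignment(
            index.ref_names, index.ref_lengths, 0, 0, empty, empty, empty, empty,
            empty, np.empty(0, dtype=np.uint8), policy,
        )
    offsets = _seed_offsets(L, index.k, max_mismatches)

    all_read, all_chrom, all_start, all_strand, all_mism = [], [], [], [], []
    for strand, smat in ((STRAND_FWD, mat), (STRAND_REV, seqs.revcomp_arr(mat))):
        seed_codes = [_codes_at(smat, off, index.k) for off in offsets]
        for ci, name in enumerate(index.ref_names):
            ref = index._enc[name]
            rlen = ref.size
            if L > rlen:
                continue
            cand_read, cand_start = [], []
            for off, codes in zip(offsets, seed_codes):
                lo = np.searchsorted(index._codes[name], codes, "left")
                hi = np.searchsorted(index._codes[name], codes, "right")
                cnt = hi - lo
                total = int(cnt.sum())
                if total == 0:
                    continue
                rep_read = np.repeat(np.arange(n), cnt)
                base = np.repeat(np.cumsum(cnt) - cnt, cnt)
                flat = np.arange(total) - base + np.repeat(lo, cnt)
                pos = index._pos[name][flat]
                cand_read.append(rep_read)
                cand_start.append(pos - off)
            if not cand_read:
                continue
            cr = np.concatenate(cand_read)
            cs = np.concatenate(cand_start)
            ok = (cs >= 0) & (cs <= rlen - L)
            cr, cs = cr[ok], cs[ok]
            key = cr.astype(np.int64) * (rlen + 1) + cs
            _, first = np.unique(key, return_index=True)
            cr, cs = cr[first], cs[first]
            for beg in range(0, cr.size, chunk):
                r = cr[beg : beg + chunk]
                s = cs[beg : beg + chunk]
                windows = ref[s[:, None] + np.arange(L)]
                mism = np.count_nonzero(windows != smat[r], axis=1)
                hit = mism <= max_mismatches
                all_read.append(r[hit])
                all_chrom.append(np.full(int(hit.sum()), ci, dtype=np.int32))
                all_start.append(s[hit])
                all_strand.append(np.full(int(hit.sum()), strand, dtype=np.int8))
                all_mism.append(mism[hit].astype(np.int16))

    if all_read:
        read_idx = np.concatenate(all_read)
        chrom_idx = np.concatenate(all_chrom)
        starts = np.concatenate(all_start)
        strands = np.concatenate(all_strand)
        mism = np.concatenate(all_mism)
    else:
        read_idx = np.empty(0, dtype=np.int64)
        chrom_idx = np.empty(0, dtype=np.int32)
        starts = np.empty(0, dtype=np.int64)
        strands = np.empty(0, dtype=np.int8)
        mism = np.empty(0, dtype=np.int16)

    n_aln = np.bincount(read_idx, minlength=n)
    category = np.full(n, BatchAlignment.CAT_MULTI, dtype=np.uint8)
    category[n_aln == 0] = BatchAlignment.CAT_UNMAPPED
    if policy in ("m1", "any-stratum"):
        category[n_aln == 1] = BatchAlignment.CAT_UNIQUE
        kept_rows = np.flatnonzero(n_aln[read_idx] == 1)
    elif policy == "best-stratum":
        best = np.full(n, np.iinfo(np.int16).max, dtype=np.int16)
        np.minimum.at(best, read_idx, mism)
        at_best = mism == best[read_idx]
        n_best = np.bincount(read_idx[at_best], minlength=n)
        uniq = (n_aln > 0) & (n_best == 1)
        category[uniq] = BatchAlignment.CAT_UNIQUE
        kept_rows = np.flatnonzero(uniq[read_idx] & at_best)
    else:
        raise ValueError(f"unknown uniqueness policy {policy!r}")

    return BatchAlignment(
        index.ref_names, index.ref_lengths, L, n, read_idx, chrom_idx,
        starts, strands, mism, category, policy, kept_rows,
    )


def batch_to_reports(
    batch: BatchAlignment, read_ids: list[str], read_seqs: list[str] | None = None
) -> list[AlignmentReport]:
    """Expand a batch result into per-read reports (sorted alignments)."""
    per_read: list[list[Alignment]] = [[] for _ in range(batch.n_reads)]
    for i in range(batch.read_idx.size):
        r = int(batch.read_idx[i])
        per_read[r].append(
            Alignment(
                batch.ref_names[int(batch.chrom_idx[i])],
                int(batch.starts[i]),
                _STRAND_CHAR[int(batch.strands[i])],
                int(batch.mismatches[i]),
                batch.read_length,
                read_ids[r],
            )
        )
    cat_names = {0: "unique", 1: "multi", 2: "unmapped"}
    reports = []
    for r in range(batch.n_reads):
        alns = sorted(per_read[r], key=Alignment.sort_key)
        cat = cat_names[int(batch.category[r])]
        reports.append(
            AlignmentReport(
                read_ids[r], alns, cat == "unique", cat,
                read_seqs[r] if read_seqs else None,
            )
        )
    return reports


def write_sam(reports: list[AlignmentReport], ref_lengths: dict[str, int], path) -> None:
    """Minimal valid SAM: every alignment of every read is written (primary
    first, the rest as secondary), unmapped reads get FLAG 4, and the
    uniqueness category is carried in a ZS tag so reports round-trip."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(l)} for n, l in ref_lengths.items()],
    }
    names = list(ref_lengths)
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rep in reports:
            if not rep.alignments:
                a = pysam.AlignedSegment(fh.header)
                a.query_name = rep.read_id
                a.flag = 4
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
                if rep.seq:
                    a.query_sequence = rep.seq
                a.set_tag("ZS", rep.category)
                fh.write(a)
                continue
            for j, aln in enumerate(rep.alignments):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = rep.read_id
                flag = 16 if aln.strand == "-" else 0
                if j > 0:
                    flag |= 256
                a.flag = flag
                a.reference_id = tid[aln.ref_name]
                a.reference_start = aln.start
                a.mapping_quality = 255
                a.cigartuples = [(0, aln.length)]
                if rep.seq is not None and j == 0:
                    a.query_sequence = (
                        seqs.revcomp(rep.seq) if aln.strand == "-" else rep.seq
                    )
                a.set_tag("NM", aln.mismatches)
                a.set_tag("ZL", aln.length)
                a.set_tag("ZS", rep.category)
                fh.write(a)


def read_sam(path) -> tuple[list[AlignmentReport], dict[str, int]]:
    """Parse a SAM stream back into per-read reports.

    Accepts both this package's output and external single-end SAM; the
    uniqueness verdict is taken from the ZS tag when present, else derived
    from the records (one primary mapped record = unique).
    """
    by_read: dict[str, AlignmentReport] = {}
    order: list[str] = []
    zs_seen: set[str] = set()
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            ref_lengths = dict(zip(fh.references, map(int, fh.lengths)))
            for rec in fh:
                rid = rec.query_name
                if rid not in by_read:
                    by_read[rid] = AlignmentReport(rid, [], False, "unmapped")
                    order.append(rid)
                rep = by_read[rid]
                if rec.has_tag("ZS"):
                    rep.category = rec.get_tag("ZS")
                    zs_seen.add(rid)
                if rec.is_unmapped:
                    continue
                length = (
                    int(rec.get_tag("ZL"))
                    if rec.has_tag("ZL")
                    else rec.query_length or rec.reference_length
                )
                rep.alignments.append(
                    Alignment(
                        rec.reference_name,
                        rec.reference_start,
                        "-" if rec.is_reverse else "+",
                        int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                        length,
                        rid,
                    )
                )
                if not rec.is_secondary and rec.query_sequence:
                    rep.seq = (
                        seqs.revcomp(rec.query_sequence)
                        if rec.is_reverse
                        else rec.query_sequence
                    )
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed SAM in {path}: {exc}") from exc
    reports = []
    for rid in order:
        rep = by_read[rid]
        rep.alignments.sort(key=Alignment.sort_key)
        if rid not in zs_seen:
            rep.category = (
                "unmapped" if not rep.alignments
                else "unique" if len(rep.alignments) == 1
                else "multi"
            )
        rep.kept = rep.category == "unique"
        reports.append(rep)
    return reports, ref_lengths
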