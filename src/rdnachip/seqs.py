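"""Sequence encoding and FASTA/FASTQ helpers shared across the pipeline.

Nucleotides are encoded as uint8 codes A=0, C=1, G=2, T=3. Ambiguity codes
are mapped to distinct sentinel values in reference (``REF_AMBIG``) and read
(``READ_AMBIG``) space so that an ambiguous base never matches anything,
including another ambiguous base.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

REF_AMBIG = np.uint8(255)
READ_AMBIG = np.uint8(254)

_BASES = "ACGT"

_ENC_REF = np.full(256, REF_AMBIG, dtype=np.uint8)
_ENC_READ = np.full(256, READ_AMBIG, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    for _c in (_b, _b.lower()):
        _ENC_REF[ord(_c)] = _i
        _ENC_READ[ord(_c)] = _i

_COMP = np.arange(256, dtype=np.uint8)
_COMP[:4] = [3, 2, 1, 0]

_DEC = np.frombuffer(b"ACGT" + b"N" * 252, dtype=np.uint8)


def encode_ref(seq: str) -> np.ndarray:
    """Encode a reference sequence; ambiguity codes become ``REF_AMBIG``."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC_REF[raw]


def encode_reads(seqs: Iterable[str]) -> np.ndarray:
    """Encode equal-length reads into an (n, L) uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("encode_reads requires equal-length reads")
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _ENC_READ[raw].reshape(len(seqs), lengths.pop())


def decode(arr: np.ndarray) -> str:
    return _DEC[np.minimum(arr, 4)].tobytes().decode("ascii")


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of encoded bases; sentinels stay sentinels."""
    return _COMP[arr][..., ::-1]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (positions, integer codes) for every unambiguous k-mer.

    Codes are base-4 polynomials of the encoded bases; windows containing
    any sentinel are dropped. Requires 2*k <= 31 to fit int64.
    """
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    valid = enc < 4
    ok = np.ones(n, dtype=bool)
    # a window is valid iff all k bases are valid
    cs = np.concatenate(([0], np.cumsum(valid.astype(np.int64))))
    ok = (cs[k:] - cs[:-k]) == k
    b = enc.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + np.where(valid[j : j + n], b[j : j + n], 0)
    pos = np.flatnonzero(ok)
    return pos, codes[pos]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path) -> tuple[list[str], list[str]]:
    ids, seqs = [], []
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            ids.append(title.split()[0])
            seqs.append(seq)
    return ids, seqs


def write_fastq(path, ids: Iterable[str], seqs: Iterable[str], qual_char: str = "I") -> None:
    """Phred+33 FASTQ with a constant quality string."""
    buf = io.StringIO()
    for rid, seq in zip(ids, seqs):
        buf.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
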