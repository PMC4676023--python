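"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (enumeration, full scans, direct
formula evaluation) and shares no code path with the implementation under
test.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_force_align(read: str, references: dict[str, str], max_mismatches: int):
    """Every-position Hamming scan on both strands.

    Returns a set of (ref_name, start, strand, mismatches).
    """
    out = set()
    for strand, query in (("+", read), ("-", revcomp(read))):
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        for name, ref in references.items():
            r = np.frombuffer(ref.encode(), dtype=np.uint8)
            L = q.size
            if L > r.size:
                continue
            ambig_ref = ~np.isin(r, np.frombuffer(b"ACGT", dtype=np.uint8))
            for s in range(r.size - L + 1):
                window = r[s : s + L]
                mism = int(np.count_nonzero((window != q) | ambig_ref[s : s + L]))
                if mism <= max_mismatches:
                    out.add((name, s, strand, mism))
    return out


def kde_double_sum(midpoints, positions, sigma: float, library_size: int) -> np.ndarray:
    """Untruncated Gaussian kernel density, full double sum."""
    midpoints = np.asarray(midpoints, dtype=float)
    positions = np.asarray(positions, dtype=float)
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    out = np.zeros(positions.size)
    for i, x in enumerate(positions):
        out[i] = norm * np.sum(np.exp(-0.5 * ((x - midpoints) / sigma) ** 2))
    return out * 1e6 / library_size


def nb_pmf(k: int, mu: float, r: float) -> float:
    p = r / (r + mu)
    return math.exp(
        math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
        + r * math.log(p) + k * math.log1p(-p)
    )


def nb_tail(observed: int, mu: float, r: float) -> float:
    """P(X >= observed) by direct pmf summation below the threshold."""
    if observed <= 0:
        return 1.0
    return 1.0 - sum(nb_pmf(k, mu, r) for k in range(observed))


def poisson_tail(observed: int, mu: float) -> float:
    if observed <= 0:
        return 1.0
    return 1.0 - sum(
        math.exp(-mu + k * math.log(mu) - math.lgamma(k + 1)) for k in range(observed)
    )


def welch_ttest(a, b) -> tuple[float, float, float]:
    """Textbook Welch t, two-sided p, and Welch-Satterthwaite df."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, p, df


def student_ttest(a, b) -> tuple[float, float, float]:
    """Classical equal-variance two-sample t-test."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, p, df


def amplicon_positions(start: int, end: int) -> int:
    """Count promoter-relative positions from start to end, skipping 0."""
    return sum(1 for p in range(start, end + 1) if p != 0)
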